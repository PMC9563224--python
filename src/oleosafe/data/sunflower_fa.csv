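name,shorthand,percent,percent_sd
Myristic,C14:0,0.03,0.00
Palmitic,C16:0,4.13,0.05
Palmitoleic,C16:1,0.04,0.00
Margaric,C17:0,0.04,0.00
Heptadecenoic,C17:1,0.02,0.00
Stearic,C18:0,3.13,0.08
Oleic,C18:1n9c,37.29,0.24
Linoleic,C18:2n6c,54.00,0.39
alpha-Linolenic,C18:3n3c,0.05,0.00
Araquidic,C20:0,0.20,0.00
Gondoic,C20:1,0.13,0.00
Eicosapentanoic,C20:5n3c,0.06,0.00
Behenic,C22:0,0.53,0.01
Docosadienoic,C22:2,0.08,0.00
Tricosylic,C23:0,0.08,0.00
Lignoceric,C24:0,0.17,0.01
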