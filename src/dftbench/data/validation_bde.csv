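substance,site,bde_calc_kcal,bde_exp_kcal
Catechin,C4',76.9,83.2
Chrysin,C7,92.6,85.4
(-)-Epicatechin,C4',82.4,82.0
(-)-Epigallocatechin,C4',79.4,82.4
Fisetin,C4',86.5,83.2
Galangin,C7,92.5,86.8
Gallic acid,C4,81.0,83.0
Luteolin,C4',78.1,81.9
Myricetin,C4',79.6,81.5
Quercetin,C4',78.6,82.0
Taxifolin,C4',86.6,82.1
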