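>CTD2B_synthetic synthetic surrogate for rat GluN2B CTD2 (1250-1482); generated sequence matching published composition/patterning statistics (FCR, NCPR, kappa, hydropathy, R/aromatic spacing); NOT the UniProt Q00960 record
SEPQNVGDSSHTVCCVNGNFRSDNDIAAGRYLIHDGGVVTTSSTTMSGPKKKNNESPVKP
ASSNNEGNQSCGSKPTTSAIMGLFKKSPPTRTSENYEMTSSKSVSSHIAYPADESTLENA
SKFVMGTLMGISAISRVGTLSVGKRSLGGTSKNANIGSSSRPKSVKRTSPHDSSEGPSDA
RESFSDIRSSAGSTPLGFRSSNSIPFTLNSRNDKSSNFEICDSEHKVTLRNSV
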