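>CTD2A_synthetic synthetic surrogate for rat GluN2A CTD2 (1243-1464); generated sequence matching published composition/patterning statistics (FCR, NCPR, kappa, hydropathy, R/aromatic spacing); NOT the UniProt Q00959 record
NVNVKDSIDSGNSTGSGVPSSLYVADDEEISSINILFQTGRKEGSPDAGGIYNDMSNNDS
SSSKSYVTTLQTDCDDSSDKSVRGMKNRKQSSATRSPSRELSGPDGLRLRTENNEVARMK
GSSTSRFGSTGRIIDEGGARQYNKNSNAESSIEGQTAYTEGVGRMSPARIEMGPRYSHEA
RTKSSRVSASKPDRFSSLGAEHVRTLSETTKYLMVMLSNTRC
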