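species,label,literature_center_cm1,search_tol_cm1,track_tol_cm1,role
ALP,alp_3398,3398,25,7.5,primary
ALP,alp_2944,2944,25,7.5,primary
ALP,alp_2889,2889,25,7.5,primary
ALP,alp_1708,1708,25,7.5,primary
ALP,alp_1624,1624,25,7.5,primary
ALP,alp_1551,1551,25,7.5,primary
ALP,alp_1531,1531,25,7.5,primary
ALP,alp_1459,1459,25,7.5,primary
ALP,alp_1418,1418,25,7.5,primary
ALP,alp_1334,1334,25,7.5,primary
ALP,alp_1215,1215,25,7.5,primary
ALP,alp_1045,1045,25,7.5,context
ALP,alp_925,925,25,7.5,context
PNPP,pnpp_1591,1591,25,7.5,primary
PNPP,pnpp_1508,1508,25,10,primary
PNPP,pnpp_1496,1496,25,7.5,primary
PNPP,pnpp_1345,1345,25,7.5,primary
PNPP,pnpp_1294,1294,25,7.5,primary
PNPP,pnpp_1606,1606,25,7.5,context
PNP,pnp_1617,1617,25,7.5,context
PNP,pnp_1595,1595,25,7.5,primary
PNP,pnp_1390,1390,25,7.5,primary
PNP,pnp_1320,1320,25,7.5,primary
Pi,pi_1077,1077,25,7.5,primary
Pi,pi_847,847,25,7.5,primary
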