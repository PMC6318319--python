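sample_id,stage,n_sequenced,n_passed,L1,L2,L3,L4,cytogenetics,placement_note
IgM_MGUS1,MGUS,26,24,15,6,3,0,Not tested,
IgM_MGUS3,MGUS,33,17,16,1,0,0,Not tested,
MGUS5,MGUS,19,7,4,3,0,0,Normal,
SMM0,SMM,84,77,0,10,0,67,t(4;14); gain 1q21; del 13q,minor fraction placed in L2 to satisfy column totals
SMM2,SMM,40,16,14,2,0,0,t(14;20); monosomy 13,t(14;20) cells restricted to L1/L2
SMM3,SMM,40,39,0,5,34,0,Trisomy 7 9 11 and 15,printed counts 4+34 sum to 38 not 39; L2 set to 5 so the row and column totals reconcile
SMM4,SMM,51,44,0,18,26,0,Trisomy 3 7 9 11 14 & 15,
NDMM3,NDMM,65,59,3,27,29,0,Trisomy 3 7 & 11; trisomy/tetrasomy 9 & 15,
NDMM5,NDMM,41,32,1,30,1,0,Trisomy 7 9 11 & 14; trisomy/tetrasomy 3 & 15; del 13q,
NDMM6,NDMM,48,47,3,41,3,0,Trisomy 3 9 11 & 15,
NDMM7,NDMM,59,54,30,24,0,0,t(11;14),t(11;14) cells restricted to L1/L2
NDMM8,NDMM,63,60,0,26,34,0,Trisomy 3 8 9 & 14; trisomy/tetrasomy 7; tetrasomy 11; gain 1q21,
RRMM1,RRMM,48,46,1,0,0,45,t(4;14); monosomy 13; del 17p,single stray cell placed in L1 to satisfy column totals
RRMM2,RRMM,50,42,1,12,28,1,t(4;14); trisomy 11 & 15; monosomy 9 & 13,cells span all four groups
RRMM4,RRMM,34,33,1,32,0,0,t(11;14) and tetraploid,t(11;14) cells restricted to L1/L2
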