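system_id,resolution,space_group,ligand_id,dH,TdS,dG,source
3MXF,1.60,P212121,JQ1,-8.42,1.22,-9.64,experiment_ITC
3U5L,1.39,P212121,08K,-6.16,2.00,-8.16,experiment_ITC
4LZR,1.85,P212121,LOC,-9.00,-2.60,-6.40,experiment_ITC
4QB3,0.94,P212121,30M,-6.62,0.93,-7.55,experiment_ITC
4XY9,1.83,P212121,43U,-6.09,0.94,-7.03,experiment_ITC
5D0C,1.49,P212121,E0B,-10.20,-2.52,-7.68,experiment_ITC
5D3S,1.75,P212121,579,-9.77,-1.73,-8.04,experiment_ITC
5DW2,1.12,P212121,5GD,-10.10,2.10,-8.00,experiment_ITC
5FBX,1.85,P212121,5W4,-15.57,-4.66,-10.90,experiment_ITC
5IGK,1.70,P212121,BMF,-11.09,-1.36,-9.73,experiment_ITC
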