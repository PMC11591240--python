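test_id,sachet_id,use_count,dP_loss_Pa,dt_s,T_tof_K
1,1,1,1400,90,296.15
2,2,1,1100,90,295.15
3,3,1,1400,90,296.15
4,2,2,2100,180,295.15
5,2,3,500,90,296.15
6,2,4,1700,180,295.65
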