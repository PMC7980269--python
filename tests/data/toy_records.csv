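species_id,population_id,maternal_line_id,treatment,seed_mass_mg,fate,emergence_day,late_retrieval_emerger
toy_sp,A,A_L1,high,5.0,emerged,4.0,False
toy_sp,A,A_L1,high,5.0,emerged,4.0,False
toy_sp,A,A_L1,low,5.0,emerged,4.0,False
toy_sp,A,A_L1,low,5.0,dead,,False
toy_sp,A,A_L2,high,6.0,emerged,4.0,False
toy_sp,A,A_L2,high,6.0,emerged,9.0,False
toy_sp,A,A_L2,low,6.0,persistent,,False
toy_sp,A,A_L2,low,6.0,dead,,False
toy_sp,A,A_L3,high,6.0,emerged,9.0,False
toy_sp,A,A_L3,high,6.0,persistent,,False
toy_sp,A,A_L3,low,6.0,persistent,,False
toy_sp,A,A_L3,low,6.0,dead,,False
toy_sp,A,A_L4,high,4.0,emerged,1.0,False
toy_sp,A,A_L4,high,4.0,emerged,16.0,False
toy_sp,A,A_L4,low,4.0,persistent,,False
toy_sp,A,A_L4,low,4.0,dead,,False
toy_sp,B,B_L1,high,4.0,emerged,9.0,False
toy_sp,B,B_L1,high,4.0,emerged,9.0,False
toy_sp,B,B_L1,low,4.0,emerged,9.0,False
toy_sp,B,B_L1,low,4.0,dead,,False
toy_sp,B,B_L2,high,5.0,emerged,9.0,False
toy_sp,B,B_L2,high,5.0,emerged,16.0,False
toy_sp,B,B_L2,low,5.0,persistent,,False
toy_sp,B,B_L2,low,5.0,dead,,False
toy_sp,B,B_L3,high,5.0,emerged,16.0,False
toy_sp,B,B_L3,high,5.0,persistent,,False
toy_sp,B,B_L3,low,5.0,persistent,,False
toy_sp,B,B_L3,low,5.0,dead,,False
toy_sp,B,B_L4,high,5.0,emerged,25.0,False
toy_sp,B,B_L4,high,5.0,dead,,False
toy_sp,B,B_L4,low,5.0,dead,,False
toy_sp,B,B_L4,low,5.0,dead,,False
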