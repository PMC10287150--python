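species_id,gr_index,n_missing
FIX-01,5,1
FIX-02,4,3
FIX-03,3,2
FIX-04,2,4
FIX-05,2,0
FIX-06,1,5
FIX-07,-2,5
FIX-08,0,1
FIX-09,1,3
FIX-10,1,2
FIX-11,-1,6
FIX-12,3,3
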