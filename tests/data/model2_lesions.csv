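lesion_id,rating_combined,rating_reference,confirmed,n_scans
M2-001,relapse,,relapse,1
M2-002,relapse,,relapse,1
M2-003,relapse,,relapse,1
M2-004,relapse,,relapse,1
M2-005,relapse,,relapse,1
M2-006,relapse,,relapse,1
M2-007,relapse,,relapse,1
M2-008,relapse,,relapse,1
M2-009,relapse,,relapse,1
M2-010,relapse,,trc,1
M2-011,trc,,trc,1
M2-012,trc,,trc,1
M2-013,trc,,trc,1
M2-014,trc,,trc,1
M2-015,trc,,trc,1
M2-016,trc,,trc,1
M2-017,trc,,trc,1
M2-018,trc,,trc,1
M2-019,trc,,trc,1
M2-020,trc,,relapse,1
M2-021,trc,,relapse,1
M2-022,trc,,relapse,1
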