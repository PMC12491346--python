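lesion_id,rating_combined,rating_reference,confirmed,n_scans
M1-001,relapse,relapse,relapse,2
M1-002,relapse,relapse,relapse,2
M1-003,relapse,relapse,relapse,2
M1-004,relapse,relapse,relapse,2
M1-005,relapse,relapse,relapse,2
M1-006,relapse,relapse,relapse,2
M1-007,relapse,relapse,relapse,2
M1-008,relapse,relapse,relapse,2
M1-009,relapse,relapse,relapse,2
M1-010,relapse,relapse,relapse,1
M1-011,relapse,relapse,relapse,1
M1-012,relapse,relapse,relapse,1
M1-013,relapse,relapse,relapse,1
M1-014,relapse,relapse,relapse,1
M1-015,relapse,relapse,relapse,1
M1-016,relapse,relapse,relapse,1
M1-017,relapse,relapse,relapse,1
M1-018,relapse,relapse,relapse,1
M1-019,relapse,relapse,relapse,1
M1-020,relapse,relapse,relapse,1
M1-021,relapse,relapse,relapse,1
M1-022,relapse,relapse,relapse,1
M1-023,relapse,relapse,relapse,1
M1-024,relapse,relapse,relapse,1
M1-025,relapse,relapse,relapse,1
M1-026,relapse,relapse,relapse,1
M1-027,relapse,relapse,relapse,1
M1-028,relapse,relapse,relapse,1
M1-029,relapse,relapse,relapse,1
M1-030,relapse,relapse,relapse,1
M1-031,relapse,relapse,relapse,1
M1-032,relapse,relapse,relapse,1
M1-033,relapse,relapse,relapse,1
M1-034,relapse,relapse,relapse,1
M1-035,relapse,relapse,relapse,1
M1-036,relapse,relapse,relapse,1
M1-037,relapse,relapse,relapse,1
M1-038,relapse,relapse,relapse,1
M1-039,relapse,relapse,relapse,1
M1-040,relapse,relapse,relapse,1
M1-041,relapse,relapse,relapse,1
M1-042,relapse,relapse,relapse,1
M1-043,relapse,relapse,relapse,1
M1-044,relapse,relapse,relapse,1
M1-045,relapse,relapse,relapse,1
M1-046,relapse,relapse,relapse,1
M1-047,relapse,relapse,relapse,1
M1-048,relapse,relapse,relapse,1
M1-049,relapse,relapse,relapse,1
M1-050,relapse,relapse,relapse,1
M1-051,relapse,relapse,relapse,1
M1-052,relapse,relapse,relapse,1
M1-053,relapse,relapse,relapse,1
M1-054,relapse,relapse,relapse,1
M1-055,trc,relapse,relapse,1
M1-056,trc,relapse,relapse,1
M1-057,trc,relapse,relapse,1
M1-058,trc,trc,relapse,1
M1-059,trc,trc,relapse,1
M1-060,trc,trc,relapse,1
M1-061,trc,trc,relapse,1
M1-062,trc,trc,relapse,1
M1-063,trc,relapse,trc,1
M1-064,trc,relapse,trc,1
M1-065,trc,relapse,trc,1
M1-066,trc,relapse,trc,1
M1-067,trc,relapse,trc,1
M1-068,trc,relapse,trc,1
M1-069,trc,relapse,trc,1
M1-070,trc,relapse,trc,1
M1-071,trc,relapse,trc,1
M1-072,trc,relapse,trc,1
M1-073,trc,relapse,trc,1
M1-074,trc,trc,trc,1
M1-075,trc,trc,trc,1
M1-076,trc,trc,trc,1
M1-077,trc,trc,trc,1
M1-078,trc,trc,trc,1
M1-079,trc,trc,trc,1
M1-080,trc,trc,trc,1
M1-081,trc,trc,trc,1
M1-082,trc,trc,trc,1
M1-083,trc,trc,trc,1
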