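id	true_group	subpop	parent_l1	parent_l2
L1-001	L1	L1_west		
L1-002	L1	L1_west		
L1-003	L1	L1_west		
L1-004	L1	L1_west		
L1-005	L1	L1_west		
L1-006	L1	L1_west		
L1-007	L1	L1_east		
L1-008	L1	L1_east		
L1-009	L1	L1_east		
L1-010	L1	L1_east		
L1-011	L1	L1_east		
L1-012	L1	L1_east		
L2-001	L2	L2_low		
L2-002	L2	L2_low		
L2-003	L2	L2_low		
L2-004	L2	L2_low		
L2-005	L2	L2_high		
L2-006	L2	L2_high		
L2-007	L2	L2_high		
L2-008	L2	L2_high		
F1-001	F1	F1	L1-011	L2-007
RIL-001	RIL	RIL	L1-002	L2-005
HG-001	hybrid_lineage	hybrid_lineage	L1-011	L2-005
HG-002	hybrid_lineage	hybrid_lineage	L1-011	L2-005
HG-003	hybrid_lineage	hybrid_lineage	L1-011	L2-005
WH-001	wheat	wheat		
WH-002	wheat	wheat		
WH-003	wheat	wheat		
WH-004	wheat	wheat		
WH-005	wheat	wheat		
WH-006	wheat	wheat		
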