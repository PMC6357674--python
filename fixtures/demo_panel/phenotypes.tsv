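id	leaf_rust	stem_rust_ttksk	hessian_fly
L1-001	R	S	R
L1-002		R	R
L1-003	R	S	R
L1-004	S	S	
L1-005	S	S	S
L1-006		S	R
L1-007	R	S	R
L1-008	S	S	R
L1-009	S	R	S
L1-010	R	S	S
L1-011	S	R	R
L1-012	R	S	S
L2-001	R		
L2-002	S		S
L2-003	S	R	
L2-004		S	
L2-005	S	R	R
L2-006	S	S	R
L2-007	S	S	S
L2-008	S	R	R
F1-001	R	S	S
RIL-001		S	S
HG-001	S		R
HG-002	S	S	R
HG-003	R	R	S
WH-001	S	S	S
WH-002	S	R	S
WH-003	S	S	S
WH-004	S	S	S
WH-005		S	S
WH-006	S	S	S
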