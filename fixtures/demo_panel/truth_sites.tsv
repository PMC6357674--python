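site	role	carriers
S3D_00029	introgression	WH-003;WH-006
S2D_00043	introgression	WH-004;WH-005
S1D_00042	introgression	WH-003;WH-006
S1D_00016	single_carrier	WH-004
S1D_00034	hybrid_private_fixed	
S2D_00036	hybrid_private_fixed	
S3D_00049	hybrid_private_fixed	
S1D_00003	hybrid_private_fixed	
S3D_00041	hybrid_private_segregating	
S3D_00018	hybrid_private_segregating	
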