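# Demo fixture

`demo_panel/` is a tiny synthetic panel (30 samples x 150 SNPs) produced by
the bundled generator with:

```python
from lineage_scope import SimConfig, write_fixture
cfg = SimConfig(seed=1234, n_l1=12, n_l2=8, n_wheat=6, n_sites=150, n_chromosomes=3,
                hybrid_group_size=3, n_f1=1, n_ril=1,
                hybrid_private_fixed=4, hybrid_private_segregating=2,
                wheat_introgression_sites=3, wheat_single_carrier_sites=1,
                wheat_introgression_carriers=2, wheat_founder_count=3)
write_fixture(cfg, "fixtures/demo_panel")
```

All files are deterministic given the seed; larger panels are generated
programmatically by the tests and analysis scripts rather than shipped.
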