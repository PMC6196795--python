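mirna	auc	sensitivity	specificity	accuracy
osa-miR1430	0.930	0.900	0.900	0.800
osa-miR156b-3p	0.978	0.900	1.000	0.900
osa-miR159a.2	0.908	0.800	1.000	0.800
osa-miR164c	0.902	0.900	0.800	0.700
osa-miR169d	0.945	0.850	0.950	0.800
osa-miR172d-5p	0.930	0.950	0.900	0.850
osa-miR319a-3p	0.950	0.950	0.950	0.900
osa-miR395a	0.957	0.850	1.000	0.850
osa-miR396g	0.913	0.800	0.950	0.700
osa-miR444b.1	0.870	0.900	0.850	0.750
osa-miR528-3p	0.890	0.800	0.900	0.700
osa-miR529a	0.931	0.850	0.950	0.800
osa-miR812q	0.986	0.900	0.950	0.850
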