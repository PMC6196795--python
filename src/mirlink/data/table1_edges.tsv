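mirna	family	response	target_no	targets
osa-miR1430	MIR169	Down	3	MYB30,NFYA,UGE-4
osa-miR156b-3p	MIR156	Down	11	49D11.4,LCAT3,NRAMP5,RPSM,SPL15,SPL16,SPL2,SPL3,SPL4,SPL9,NCED1
osa-miR159a.2	MIR159	Down	3	49D11.4,MYB4,MYB39
osa-miR164c	MIR164	Down	4	CML22,CUC,NAC22,TCP8
osa-miR169d	MIR169	Down	6	CBF,DREB,HAP2D,NAAT2,NFYA,UGE-4
osa-miR172d-5p	MIR172	Down	7	AP2D2,AP2D23,AP2D4,ARF9,bZIP,GT43A,JMJ705
osa-miR319a-3p	MIR159	Down	5	49D11.4,MYB4,MYB59,TCP14,TCP7
osa-miR395a	MIR395	Down	4	ATPS3,P0651G05.2,RRF,URH2
osa-miR396g	MIR396	Down	9	6PGL 1,P0651G05.2,PMP22,RGA2,RHL1,RPM1,RRM_SF,TPT
osa-miR444b.1	MIR444	Down	3	MADS2,MADS27,UEL-1
osa-miR528-3p	MIR528	Up	5	AO,DCL1,DWARF-3,IAR,SODCC.1
osa-miR529a	MIR529	Down	4	ACOX4,NUS1,SPL2,SPL9
osa-miR812q	MIR812	Up	3	CIPK10,DWARF-3,ERF
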