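gene	snp	chrom	beta_fwd	se_fwd	p_fwd	beta_rev	se_rev	p_rev
CCDC21	rs869683	1	0.571	0.197	3.67E-03	-0.005	0.024	8.46E-01
S100A13	rs9661993	1	-0.166	0.062	7.35E-03	-0.097	0.057	9.15E-02
GCNT1	rs11144929	9	1.503	0.606	1.32E-02	-0.018	0.03	5.62E-01
CLC	rs17709471	19	0.467	0.198	1.80E-02	-0.061	0.082	4.58E-01
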