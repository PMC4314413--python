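term	count	p
Cell cycle	15	1.88E-05
Oocyte meiosis	14	2.12E-05
ECM-receptor interaction	11	1.85E-04
Progesterone-mediated oocyte maturation	11	2.25E-04
Complement and coagulation cascades	8	0.004395
Focal adhesion	14	0.007100
Aldosterone-regulated sodium reabsorption	5	0.033673
Pathways in cancer	17	0.036557
Prostate cancer	7	0.050592
p53 signaling pathway	6	0.052858
Ether lipid metabolism	4	0.086840
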