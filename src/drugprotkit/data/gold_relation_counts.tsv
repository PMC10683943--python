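rel_type	training	development	test
ANTAGONIST	972	218	154
AGONIST	658	131	101
AGONIST-ACTIVATOR	29	10	0
AGONIST-INHIBITOR	13	2	3
DIRECT-REGULATOR	2247	458	429
ACTIVATOR	1428	246	334
INHIBITOR	5388	1150	1051
INDIRECT-DOWNREGULATOR	1329	332	304
INDIRECT-UPREGULATOR	1378	302	277
PART-OF	885	257	228
PRODUCT-OF	920	158	181
SUBSTRATE	2003	494	419
SUBSTRATE_PRODUCT-OF	24	3	10
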