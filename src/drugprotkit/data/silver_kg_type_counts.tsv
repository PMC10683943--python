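rel_type	predictions	unique_edges
ANTAGONIST	4597943	533536
AGONIST	3315925	463888
AGONIST-ACTIVATOR	25596	6468
AGONIST-INHIBITOR	36171	4683
DIRECT-REGULATOR	13572608	2425063
ACTIVATOR	13727350	2034690
INHIBITOR	34863037	3636934
INDIRECT-DOWNREGULATOR	18066689	1882009
INDIRECT-UPREGULATOR	19091394	2277607
PART-OF	17711521	2174233
PRODUCT-OF	7341295	1248229
SUBSTRATE	14497706	2668567
SUBSTRATE_PRODUCT-OF	16886	11499
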