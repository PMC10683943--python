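etype	training	development	test
GENE	43255	9005	9515
CHEMICAL	46274	9853	9434
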