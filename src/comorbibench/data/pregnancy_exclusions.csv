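system,pattern_type,pattern
ICD9,range,630-679
ICD9,prefix,V27
ICD10,range,O00-O99
ICD10,prefix,Z37
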