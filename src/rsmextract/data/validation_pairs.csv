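response,experimental,experimental_sd,predicted
TPC,24.25,1.02,23.97
TFC,23.98,0.65,23.39
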