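((((tomato:7.3,potato:7.3)ATPt:8.2,eggplant:15.5)ATE:4.1,pepper:19.6)ATP:4.1,nicotiana:23.7)ATN;
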