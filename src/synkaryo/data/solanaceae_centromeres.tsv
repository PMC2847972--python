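chromosome	position_cM	left_marker	right_marker
T1	47.5	T1m10	T1m11
T2	47.5	T2m10	T2m11
T3	47.5	T3m10	T3m11
T4	47.5	T4m10	T4m11
T5	47.5	T5m10	T5m11
T6	47.5	T6m10	T6m11
T7	47.5	T7m10	T7m11
T8	47.5	T8m10	T8m11
T9	47.5	T9m10	T9m11
T10	47.5	T10m10	T10m11
T11	47.5	T11m10	T11m11
T12	47.5	T12m10	T12m11
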