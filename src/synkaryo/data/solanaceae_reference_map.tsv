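species	chromosome	marker	position_cM	confidence
tomato	T1	T1m01	0	high
tomato	T1	T1m02	5	high
tomato	T1	T1m03	10	high
tomato	T1	T1m04	15	high
tomato	T1	T1m05	20	high
tomato	T1	T1m06	25	high
tomato	T1	T1m07	30	high
tomato	T1	T1m08	35	high
tomato	T1	T1m09	40	high
tomato	T1	T1m10	45	high
tomato	T1	T1m11	50	high
tomato	T1	T1m12	55	high
tomato	T1	T1m13	60	high
tomato	T1	T1m14	65	high
tomato	T1	T1m15	70	high
tomato	T1	T1m16	75	high
tomato	T1	T1m17	80	high
tomato	T1	T1m18	85	high
tomato	T1	T1m19	90	high
tomato	T1	T1m20	95	high
tomato	T2	T2m01	0	high
tomato	T2	T2m02	5	high
tomato	T2	T2m03	10	high
tomato	T2	T2m04	15	high
tomato	T2	T2m05	20	high
tomato	T2	T2m06	25	high
tomato	T2	T2m07	30	high
tomato	T2	T2m08	35	high
tomato	T2	T2m09	40	high
tomato	T2	T2m10	45	high
tomato	T2	T2m11	50	high
tomato	T2	T2m12	55	high
tomato	T2	T2m13	60	high
tomato	T2	T2m14	65	high
tomato	T2	T2m15	70	high
tomato	T2	T2m16	75	high
tomato	T2	T2m17	80	high
tomato	T2	T2m18	85	high
tomato	T2	T2m19	90	high
tomato	T2	T2m20	95	high
tomato	T3	T3m01	0	high
tomato	T3	T3m02	5	high
tomato	T3	T3m03	10	high
tomato	T3	T3m04	15	high
tomato	T3	T3m05	20	high
tomato	T3	T3m06	25	high
tomato	T3	T3m07	30	high
tomato	T3	T3m08	35	high
tomato	T3	T3m09	40	high
tomato	T3	T3m10	45	high
tomato	T3	T3m11	50	high
tomato	T3	T3m12	55	high
tomato	T3	T3m13	60	high
tomato	T3	T3m14	65	high
tomato	T3	T3m15	70	high
tomato	T3	T3m16	75	high
tomato	T3	T3m17	80	high
tomato	T3	T3m18	85	high
tomato	T3	T3m19	90	high
tomato	T3	T3m20	95	high
tomato	T4	T4m01	0	high
tomato	T4	T4m02	5	high
tomato	T4	T4m03	10	high
tomato	T4	T4m04	15	high
tomato	T4	T4m05	20	high
tomato	T4	T4m06	25	high
tomato	T4	T4m07	30	high
tomato	T4	T4m08	35	high
tomato	T4	T4m09	40	high
tomato	T4	T4m10	45	high
tomato	T4	T4m11	50	high
tomato	T4	T4m12	55	high
tomato	T4	T4m13	60	high
tomato	T4	T4m14	65	high
tomato	T4	T4m15	70	high
tomato	T4	T4m16	75	high
tomato	T4	T4m17	80	high
tomato	T4	T4m18	85	high
tomato	T4	T4m19	90	high
tomato	T4	T4m20	95	high
tomato	T5	T5m01	0	high
tomato	T5	T5m02	5	high
tomato	T5	T5m03	10	high
tomato	T5	T5m04	15	high
tomato	T5	T5m05	20	high
tomato	T5	T5m06	25	high
tomato	T5	T5m07	30	high
tomato	T5	T5m08	35	high
tomato	T5	T5m09	40	high
tomato	T5	T5m10	45	high
tomato	T5	T5m11	50	high
tomato	T5	T5m12	55	high
tomato	T5	T5m13	60	high
tomato	T5	T5m14	65	high
tomato	T5	T5m15	70	high
tomato	T5	T5m16	75	high
tomato	T5	T5m17	80	high
tomato	T5	T5m18	85	high
tomato	T5	T5m19	90	high
tomato	T5	T5m20	95	high
tomato	T6	T6m01	0	high
tomato	T6	T6m02	5	high
tomato	T6	T6m03	10	high
tomato	T6	T6m04	15	high
tomato	T6	T6m05	20	high
tomato	T6	T6m06	25	high
tomato	T6	T6m07	30	high
tomato	T6	T6m08	35	high
tomato	T6	T6m09	40	high
tomato	T6	T6m10	45	high
tomato	T6	T6m11	50	high
tomato	T6	T6m12	55	high
tomato	T6	T6m13	60	high
tomato	T6	T6m14	65	high
tomato	T6	T6m15	70	high
tomato	T6	T6m16	75	high
tomato	T6	T6m17	80	high
tomato	T6	T6m18	85	high
tomato	T6	T6m19	90	high
tomato	T6	T6m20	95	high
tomato	T7	T7m01	0	high
tomato	T7	T7m02	5	high
tomato	T7	T7m03	10	high
tomato	T7	T7m04	15	high
tomato	T7	T7m05	20	high
tomato	T7	T7m06	25	high
tomato	T7	T7m07	30	high
tomato	T7	T7m08	35	high
tomato	T7	T7m09	40	high
tomato	T7	T7m10	45	high
tomato	T7	T7m11	50	high
tomato	T7	T7m12	55	high
tomato	T7	T7m13	60	high
tomato	T7	T7m14	65	high
tomato	T7	T7m15	70	high
tomato	T7	T7m16	75	high
tomato	T7	T7m17	80	high
tomato	T7	T7m18	85	high
tomato	T7	T7m19	90	high
tomato	T7	T7m20	95	high
tomato	T8	T8m01	0	high
tomato	T8	T8m02	5	high
tomato	T8	T8m03	10	high
tomato	T8	T8m04	15	high
tomato	T8	T8m05	20	high
tomato	T8	T8m06	25	high
tomato	T8	T8m07	30	high
tomato	T8	T8m08	35	high
tomato	T8	T8m09	40	high
tomato	T8	T8m10	45	high
tomato	T8	T8m11	50	high
tomato	T8	T8m12	55	high
tomato	T8	T8m13	60	high
tomato	T8	T8m14	65	high
tomato	T8	T8m15	70	high
tomato	T8	T8m16	75	high
tomato	T8	T8m17	80	high
tomato	T8	T8m18	85	high
tomato	T8	T8m19	90	high
tomato	T8	T8m20	95	high
tomato	T9	T9m01	0	high
tomato	T9	T9m02	5	high
tomato	T9	T9m03	10	high
tomato	T9	T9m04	15	high
tomato	T9	T9m05	20	high
tomato	T9	T9m06	25	high
tomato	T9	T9m07	30	high
tomato	T9	T9m08	35	high
tomato	T9	T9m09	40	high
tomato	T9	T9m10	45	high
tomato	T9	T9m11	50	high
tomato	T9	T9m12	55	high
tomato	T9	T9m13	60	high
tomato	T9	T9m14	65	high
tomato	T9	T9m15	70	high
tomato	T9	T9m16	75	high
tomato	T9	T9m17	80	high
tomato	T9	T9m18	85	high
tomato	T9	T9m19	90	high
tomato	T9	T9m20	95	high
tomato	T10	T10m01	0	high
tomato	T10	T10m02	5	high
tomato	T10	T10m03	10	high
tomato	T10	T10m04	15	high
tomato	T10	T10m05	20	high
tomato	T10	T10m06	25	high
tomato	T10	T10m07	30	high
tomato	T10	T10m08	35	high
tomato	T10	T10m09	40	high
tomato	T10	T10m10	45	high
tomato	T10	T10m11	50	high
tomato	T10	T10m12	55	high
tomato	T10	T10m13	60	high
tomato	T10	T10m14	65	high
tomato	T10	T10m15	70	high
tomato	T10	T10m16	75	high
tomato	T10	T10m17	80	high
tomato	T10	T10m18	85	high
tomato	T10	T10m19	90	high
tomato	T10	T10m20	95	high
tomato	T11	T11m01	0	high
tomato	T11	T11m02	5	high
tomato	T11	T11m03	10	high
tomato	T11	T11m04	15	high
tomato	T11	T11m05	20	high
tomato	T11	T11m06	25	high
tomato	T11	T11m07	30	high
tomato	T11	T11m08	35	high
tomato	T11	T11m09	40	high
tomato	T11	T11m10	45	high
tomato	T11	T11m11	50	high
tomato	T11	T11m12	55	high
tomato	T11	T11m13	60	high
tomato	T11	T11m14	65	high
tomato	T11	T11m15	70	high
tomato	T11	T11m16	75	high
tomato	T11	T11m17	80	high
tomato	T11	T11m18	85	high
tomato	T11	T11m19	90	high
tomato	T11	T11m20	95	high
tomato	T12	T12m01	0	high
tomato	T12	T12m02	5	high
tomato	T12	T12m03	10	high
tomato	T12	T12m04	15	high
tomato	T12	T12m05	20	high
tomato	T12	T12m06	25	high
tomato	T12	T12m07	30	high
tomato	T12	T12m08	35	high
tomato	T12	T12m09	40	high
tomato	T12	T12m10	45	high
tomato	T12	T12m11	50	high
tomato	T12	T12m12	55	high
tomato	T12	T12m13	60	high
tomato	T12	T12m14	65	high
tomato	T12	T12m15	70	high
tomato	T12	T12m16	75	high
tomato	T12	T12m17	80	high
tomato	T12	T12m18	85	high
tomato	T12	T12m19	90	high
tomato	T12	T12m20	95	high
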