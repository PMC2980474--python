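S000	2
S001	2
S002	2
S003	2
S004	2
S005	2
S006	2
S007	2
S008	3
S009	3
S010	3
S011	3
S012	3
S013	3
S014	3
S015	3
S016	1
S017	1
S018	1
S019	1
S020	1
S021	1
S022	1
S023	1
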