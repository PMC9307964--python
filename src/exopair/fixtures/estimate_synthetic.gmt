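STROMAL_SIGNATURE_SYNTHETIC	synthetic_placeholder_members	STRG000	STRG001	STRG002	STRG003	STRG004	STRG005	STRG006	STRG007	STRG008	STRG009	STRG010	STRG011	STRG012	STRG013	STRG014	STRG015	STRG016	STRG017	STRG018	STRG019	STRG020	STRG021	STRG022	STRG023	STRG024	STRG025	STRG026	STRG027	STRG028	STRG029
IMMUNE_SIGNATURE_SYNTHETIC	synthetic_placeholder_members	IMMG000	IMMG001	IMMG002	IMMG003	IMMG004	IMMG005	IMMG006	IMMG007	IMMG008	IMMG009	IMMG010	IMMG011	IMMG012	IMMG013	IMMG014	IMMG015	IMMG016	IMMG017	IMMG018	IMMG019	IMMG020	IMMG021	IMMG022	IMMG023	IMMG024	IMMG025	IMMG026	IMMG027	IMMG028	IMMG029
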