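cell_type	LSMetacell	hdWGCNA	Metacell2	MetaQ	SEACells	SuperCell	Primary
EN	3742	3736	2680	3270	2827	3460	3732
IN	3946	2983	1460	2173	1704	3357	3793
OC	3336	3033	3033	2762	1664	3042	2831
AC	3318	2359	2359	1657	2358	2303	3203
MC	3753	1735	3070	2141	1345	2969	3642
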