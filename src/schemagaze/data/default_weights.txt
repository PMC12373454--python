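own2	0.39868412879413295
own3	0.9562022928645691
own4	2.946585531612289
opp2	0.5844966032991566
opp3	3.562011939177327
center	0.31029145193989516
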