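INFLAMMATION_LIKE_synthetic	synthetic toy gene-set collection for the enrichment example	G00001	G00002	G00003	G00010	G00011	G00012	G00200	G00201	G00202	G00203
MYOGENESIS_LIKE_synthetic	synthetic toy gene-set collection for the enrichment example	G00065	G00066	G00067	G00068	G00069	G00070	G00071	G00300	G00301	G00302	G00303	G00304
CELL_CYCLE_LIKE_synthetic	synthetic toy gene-set collection for the enrichment example	G00400	G00401	G00402	G00403	G00404	G00405	G00406	G00407	G00408	G00409
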