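HOXA_CLUSTER	HOXA homeobox cluster (chromosome 7p15) gene symbols	HOXA1	HOXA2	HOXA3	HOXA4	HOXA5	HOXA6	HOXA7	HOXA9	HOXA10	HOXA11	HOXA13
HOXB_CLUSTER	HOXB homeobox cluster (chromosome 17q21) gene symbols	HOXB1	HOXB2	HOXB3	HOXB4	HOXB5	HOXB6	HOXB7	HOXB8	HOXB9	HOXB13
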