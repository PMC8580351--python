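{
 "driver_catalog.csv": "10bc69a10c2e2a9dca11ac3376b735a5fd1e7e3775a1732455a207b9debb4420",
 "params_female.csv": "945a5df9c9bb1f0b68ca586deed79d393c161003557336b25ab8028efbb0ca24",
 "params_male.csv": "fe9997bf9511ac71291ed39dadd1023a253a8bd5b1654debef7456a4324af4ae",
 "params_pooled.csv": "f5fba064e2813f36b889a07e5d52cd17dfc4693f92cfb8df6e7dc5f587f4bcfd"
}
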