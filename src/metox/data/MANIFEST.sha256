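56b295f4047a4092a0ce2086b9a1f36d55e9529b15e9fc576a6a590001a4576c  cst_events.tsv
852298bbacb42b70d70ddb18d76608e3ae0833bc1e8e7a9c286ab4c24bef4069  crystal_example.tsv
50f010d85db946ec25be3a38b01dce46e32adf1b1527fb38dedbbbb7397285a8  internal_oxidation.tsv
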