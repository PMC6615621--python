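{
 "source": "minvent built-in SYNTHETIC spirometry reference table (not GLI-2012; plausible magnitudes for tests and simulation only)",
 "version": "1",
 "age_range": [
  4,
  80
 ]
}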