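strain	three_prime_only
Seattle	3
Montpellier	11
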