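strain	site_label
Seattle	3A
Seattle	6A
Seattle	12F*
Seattle	19E
Seattle	44D
Seattle	62D
Seattle	78C*
Seattle	84B
Seattle	86A*
Seattle	89F
Seattle	92A
Seattle	94C
Seattle	97A
Seattle	102A*
Montpellier	12F*
Montpellier	17D
Montpellier	25D
Montpellier	50A
Montpellier	57D
Montpellier	64D
Montpellier	67D
Montpellier	75C
Montpellier	86A*
Montpellier	91A
Montpellier	92A
Montpellier	98A
Montpellier	98B*
Montpellier	99A
Montpellier	99B
Montpellier	102A*
FlyBase	11A
FlyBase	12F*
FlyBase	19E
FlyBase	43E
FlyBase	66D
FlyBase	78C*
FlyBase	86A*
FlyBase	98B2*
FlyBase	98B8
FlyBase	102A*
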