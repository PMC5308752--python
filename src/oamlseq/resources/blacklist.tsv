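chrom	pos	ref	alt	note
chr9	139390945	TC	T	recurrent NOTCH1 1bp-deletion artifact not confirmed by resequencing
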