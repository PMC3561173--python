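# Loop initiation free energies, kcal/mol at 37 C.  Turner-1999-derived,
# rounded to 0.1 kcal/mol; sizes beyond the table are extended by the
# Jacobson-Stockmayer form dG(n) = dG(n_max) + 1.08 * ln(n / n_max).
# Multiloops carry a flat closing penalty plus a per-branch penalty
# (closing helix counted as a branch); unpaired multiloop bases are free.
# kind	size	dG
hairpin	3	5.4
hairpin	4	5.6
hairpin	5	5.7
hairpin	6	5.4
hairpin	7	6.0
hairpin	8	5.5
hairpin	9	6.4
bulge	1	3.8
bulge	2	2.8
bulge	3	3.2
bulge	4	3.6
bulge	5	4.0
bulge	6	4.4
internal	2	4.1
internal	3	5.1
internal	4	4.9
internal	5	5.3
internal	6	5.7
multiloop_init	0	3.4
multiloop_branch	0	0.4
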