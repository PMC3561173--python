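# Nearest-neighbor helix stacking free energies, kcal/mol at 37 C.
# Turner-1999-derived values rounded to 0.1 kcal/mol; reduced model v1.
# outer = 5' pair (i,j), inner = stacked pair (i+1,j-1); table satisfies
# stack(outer, inner) == stack(reverse(inner), reverse(outer)).
# outer	inner	dG
AU	AU	-0.9
AU	CG	-2.2
AU	GC	-2.1
AU	GU	-0.6
AU	UA	-1.1
AU	UG	-1.4
CG	AU	-2.1
CG	CG	-3.3
CG	GC	-2.4
CG	GU	-1.4
CG	UA	-2.1
CG	UG	-2.1
GC	AU	-2.4
GC	CG	-3.4
GC	GC	-3.3
GC	GU	-1.5
GC	UA	-2.2
GC	UG	-2.5
GU	AU	-1.3
GU	CG	-2.5
GU	GC	-2.1
GU	GU	-0.5
GU	UA	-1.4
GU	UG	1.3
UA	AU	-1.3
UA	CG	-2.4
UA	GC	-2.1
UA	GU	-1.0
UA	UA	-0.9
UA	UG	-1.3
UG	AU	-1.0
UG	CG	-1.5
UG	GC	-1.4
UG	GU	0.3
UG	UA	-0.6
UG	UG	-0.5
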