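"""Score body-site niche association of strain haplotypes.

Simulates haplotypes for one species at two oral sites, where each site's
strains descend from a site-specific ancestor (between-site divergence 0.5
substitutions/site vs 0.01 within), computes Kimura two-parameter distances,
and evaluates the niche-association score A: the maximum over directed site
pairs (u, v) of D(u, v) = (b - a) / max(b, a), with a the mean within-u and
b the mean u-to-v strain divergence.  A near 1 means site-specific
subspecies clades; a null (single shared ancestor) stays near 0.
"""

from microdyn import SimulationSpec, niche_association_score, simulate_strain_clades

spec = SimulationSpec(seed=7)

structured = simulate_strain_clades(spec, samples_per_site=8)
result = niche_association_score(structured.distance_matrix)
print(f"site-structured clades : A = {result.score:.3f}")
for (u, v), d in sorted(result.pair_scores.items()):
    print(f"  D({u} -> {v}) = {d:.3f}")

null = simulate_strain_clades(spec, samples_per_site=8, structured=False)
print(f"shared-ancestor null   : A = {niche_association_score(null.distance_matrix).score:.3f}")
print()
print("A >= ~0.9 indicates discrete site-specific subspecies clades;")
print("values near 0 mean strains mix freely across body sites.")
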