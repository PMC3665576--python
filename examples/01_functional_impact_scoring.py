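"""Score residue substitutions against a protein family alignment.

Builds a small synthetic family alignment with known conserved columns,
then scores substitutions at a conserved and at a variable position.
Positive FIS means the destination residue is rarer than the source in the
family and in the query's subfamily — the signature of a functionally
disruptive change; scores near or below zero mark tolerated changes.
"""

from mutsel import build_ensemble, gen_alignment, score_mutation

pairs, labels, conserved_mask = gen_alignment(
    n_seqs=40, n_cols=60, conserved_fraction=0.25, n_subfamilies=3, seed=7,
)
ensemble = build_ensemble(pairs, query_id=pairs[0][0], subfamily_labels=labels)
query = pairs[0][1]

conserved_pos = int(conserved_mask.argmax()) + 1          # 1-based
variable_pos = int((~conserved_mask).argmax()) + 1

for name, pos in [("conserved", conserved_pos), ("variable", variable_pos)]:
    ref = query[pos - 1]
    col_counts = ensemble.counts[pos - 1, :20]
    by_freq = sorted(
        (a for a in "ACDEFGHIKLMNPQRSTVWY" if a != ref),
        key=lambda a: -col_counts["ACDEFGHIKLMNPQRSTVWY".index(a)],
    )
    for alt, kind in [(by_freq[-1], "rare"), (by_freq[0], "common")]:
        res = score_mutation(ensemble, pos, ref, alt)
        print(f"{name} column, {ref}{pos}{alt} (toward {kind:>6} residue): "
              f"FIS = {res.fis:+.3f} "
              f"(family {res.family_term:+.3f}, subfamily {res.subfamily_term:+.3f})")

print("\nSubstitutions toward residues unobserved in a conserved column score")
print("high; substitutions toward residues evolution already tolerates do not.")
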