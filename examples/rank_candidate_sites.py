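"""End-to-end site nomination on a synthetic extein bundle.

A synthetic extein is generated with one planted insertion site that looks
native-like (conserved PSSM column, near annotated active-site residues,
one residue from a sheet/loop junction) among 14 decoy C/S/T sites.  The
predictor recomputes all features from the bundle and ranks candidates by
how many cutoff calls they satisfy.
"""

from inteinsite import PredictorConfig, generate_synthetic_case, predict_extein

case = generate_synthetic_case(seed=11)
print(f"extein {case.extein.id}: {len(case.extein)} residues, "
      f"planted site at {case.planted_site.position}")

verdicts = predict_extein(
    case.extein,
    pssm=case.pssm,
    structure=case.structure,
    config=PredictorConfig(combined_rule=frozenset({"conservation", "distance"})),
)

print("\ntop candidates (satisfied-calls, conservation rank, distance [A]):")
for v in verdicts[:5]:
    f = v.features
    mark = " <- planted" if f.site.position == case.planted_site.position else ""
    print(
        f"  {f.site.plus_one_residue}{f.site.position:<4d} "
        f"calls={v.n_satisfied}  cons={f.conservation_rank:.2f}  "
        f"dist={f.distance_to_functional_site:5.1f}{mark}"
    )
print("\nthe planted site tops the list: its PSSM column is the most conserved")
print("candidate (rank 1.0) and it sits a few Angstrom from the annotation.")
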