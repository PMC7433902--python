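"""Build a mitotic asymmetry timeline from a simulated population.

Draws centrosome records per stage from prescribed category probabilities
(the structure of the daughter-marker localization timeline) and tabulates
the per-stage category fractions — the numbers behind a timeline bar chart.
"""

from centroasym import inverted_fraction, simulate_population, timeline_fractions

# a wild-type-like progression: marker moves from both centrioles
# (transition) toward daughter-only localization (complete) during mitosis
profiles = {
    "prophase": {"transition": 0.7, "strong": 0.3},
    "prometaphase": {"transition": 0.3, "strong": 0.6, "complete": 0.1},
    "metaphase": {"strong": 0.5, "complete": 0.5},
    "anaphase": {"strong": 0.2, "complete": 0.8},
    "telophase": {"single_positive": 0.6, "complete": 0.4},
}
records = simulate_population(profiles, n_per_stage=120, seed=3)

table = timeline_fractions(records)
cols = ["stage", "n", "single_positive", "transition", "strong", "complete"]
print(table[cols].round(3).to_string(index=False))

frac, n_inv, n = inverted_fraction(records)
print(f"\ninverted asymmetry (ratio < 1) in metaphase+anaphase: "
      f"{100 * frac:.1f}% ({n_inv}/{n})")
print("each row's fractions estimate the drawn per-stage probabilities; "
      "inverted ratios are rare because draws start at ratio 0.1-2 only "
      "in the transition class")
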