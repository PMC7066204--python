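"""Two-spot assay: how degradation logic sets the sensitive range.

A drop of cells sits beside an equal drop of attractant on an open field.
A run scores positive when at least twice as many cells end up in the
attractant-facing half of the drop as in the far half.  Compares the three
degradation logics at a low (1 uM) and a high (300 uM) spot concentration:

* no degradation     — works at low spots, saturates at high ones;
* always-on          — extends the top of the range but destroys the weak
                       low-concentration signal;
* occupancy-induced  — enzymes switch on (Hill factor, vb=0.05, ki=0.4,
                       h=2) only when receptors have been busy, combining
                       the low floor of no-degradation with the high
                       ceiling of always-on.
"""

from sggrad import build_two_spot, run_scenario

for conc in (1_000.0, 300_000.0):
    print(f"\nattractant spot {conc/1000:g} uM:")
    for logic in ("none", "always_on", "induced"):
        spec = build_two_spot(conc, degradation=logic, seed=4)
        _, score = run_scenario(spec)
        verdict = "POSITIVE" if score.two_spot_positive else "negative"
        print(
            f"  degradation {logic:>9s}: front/back = "
            f"{score.front_count}/{score.back_count}  -> {verdict}"
        )

print(
    "\nInduced degradation is the only logic positive at both extremes,"
    "\nwhich is what widens the assay's dynamic range."
)
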