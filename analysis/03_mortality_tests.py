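"""Test whether the estimated aging rate predicts mortality.

Three procedures on the simulated cohort and its estimated PARs:
a Cox proportional-hazards fit of survival on log2(PAR) + age + sex,
the randomized age-matched dPAR test with its label-permutation control
(2,000 repetitions each), and the lifespan-PAR correlation among the
deceased. Outputs cox.json and match_summary.json under results/.

Run after 02:  python analysis/03_mortality_tests.py
"""

import json
from pathlib import Path

import pandas as pd

import physioage as pa

OUT = Path("results")
SEED = 20260929
REPS = 2000


def main() -> None:
    cohort = pa.read_cohort(OUT / "cohort" / "traits.tsv", OUT / "cohort" / "meta.tsv")
    par = pd.read_csv(OUT / "par.tsv", sep="\t", index_col="id")["par"]

    cox = pa.fit_cox(cohort.meta, par)
    (OUT / "cox.json").write_text(json.dumps({
        "table": json.loads(cox.frame().to_json(orient="index")),
        "n": cox.n, "n_deaths": cox.n_deaths, "person_years": cox.person_years,
    }, indent=2))
    hr2 = cox.hazard_ratio["log2_par"]
    print(f"Cox: {cox.n_deaths} deaths, {cox.person_years:.0f} person-years")
    print(f"  log2(PAR): coef {cox.coef['log2_par']:.2f} -> a two-fold higher "
          f"aging rate multiplies the hazard by {hr2:.2f} (p = {cox.p['log2_par']:.3g})")

    matched = pa.age_matched_test(cohort.meta, par, reps=REPS, seed=SEED)
    control = pa.randomized_control(cohort.meta, par, reps=REPS, seed=SEED)
    r, p, n_dead = pa.lifespan_correlation(cohort.meta, par)
    summary = {"matched": matched.summary(), "control": control.summary(),
               "lifespan_par": {"r": r, "p": p, "n": n_dead}}
    (OUT / "match_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"age-matched test: {100 * matched.frac_significant:.1f}% of {REPS} reps "
          f"significant (p<0.05), mean dPAR {matched.mean_delta_par:.4f}, "
          f"{100 * matched.frac_positive:.1f}% positive")
    print(f"randomized control: {100 * control.frac_significant:.1f}% significant, "
          f"mean dPAR {control.mean_delta_par:.4f}, "
          f"{100 * control.frac_positive:.1f}% positive")
    print(f"lifespan vs PAR among {n_dead} deceased: r = {r:.3f}")


if __name__ == "__main__":
    main()
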