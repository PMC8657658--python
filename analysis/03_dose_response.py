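"""Dose-response confirmation of the lead compounds.

One crossed hit is dropped as toxic (mirroring the screen's auranofin
exclusion, supplied here as an explicit exclusion list).  The
remaining leads get simulated percent-of-vehicle responses at 1, 2.5,
5 and 10 uM in triplicate; each is fit with the four-parameter
logistic and confirmed by one-way ANOVA across dose groups with
Bonferroni pairwise comparisons.
"""

import json
from pathlib import Path

from cystirep import integrate
from cystirep import synthdata as sd
from cystirep.pipeline import default_study

SEED = 7
OUT = Path("results/analysis")


def main() -> None:
    spec = default_study(SEED)
    crossed = (OUT / "crossed_hits.txt").read_text().split()
    leads = sorted(set(crossed) - {spec.toxic_lead})
    print(f"{len(crossed)} crossed hits; excluded toxic: {spec.toxic_lead}; {len(leads)} leads")

    data, truth = sd.simulate_dose_response(leads, seed=spec.dose_seed)
    sd.write_table(data, OUT / "dose_response.csv", sep=",", schema="dose-response")

    fits = {}
    for cid, grp in data.groupby("compound_id"):
        fit = integrate.fit_4pl(grp["dose_uM"], grp["response_percent"], compound_id=cid)
        groups = [g["response_percent"].to_numpy() for _, g in grp.groupby("dose_uM")]
        anova = integrate.confirm_by_anova(groups)
        true_ec50 = float(truth.set_index("compound_id").loc[cid, "ec50"])
        fits[cid] = {
            "ec50": fit.ec50, "hill": fit.hill, "top": fit.top, "bottom": fit.bottom,
            "converged": fit.converged, "anova_p": anova.p, "true_ec50": true_ec50,
        }
        status = f"EC50 {fit.ec50:.2f} uM (true {true_ec50:.2f})" if fit.converged else "not converged"
        print(f"  {cid}: {status}, ANOVA p = {anova.p:.2e}")
    (OUT / "dose_response_fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
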