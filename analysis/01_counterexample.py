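"""Degeneracy counterexample: a truly nonzero path that every composite
scheme estimates at exactly zero.

Builds the parallel-measures population model (two exogenous latents,
variance 1, covariance -2/3; three indicators per latent with loadings 1
and error variances 1; disturbance variance 1), picks the structural
coefficients with the degeneracy solver so the composite plim of the
first path vanishes while the true coefficient is 0.25, and runs CB-SEM
plus the four composite methods on the population covariance matrix.

Writes results/counterexample_estimates.csv and prints the side-by-side
estimates and z-statistics.
"""

from pathlib import Path

import pandas as pd

import compositebias as cb
from compositebias.compare import Problem

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model = cb.make_counterexample(gamma1=0.25)
    truth = {f"{s}->{d}": c for s, d, c in model.structural}
    print("true structural coefficients:", truth)

    S = cb.implied_indicator_cov(model)
    zt = cb.compare_methods(
        [Problem(label="counterexample", data=S, model=model, nominal_n=500)],
        scaling="marker")
    est = zt.estimates.droplevel("problem")
    z = zt.z.droplevel("problem")
    table = pd.concat({"estimate": est, "z": z}, axis=1)
    table.insert(0, ("true", "coef"), pd.Series(truth))

    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "counterexample_estimates.csv", float_format="%.6f")
    print(table.round(4).to_string())
    g1 = est.loc["eta_ind1->eta_dep"]
    print(f"\ncomposite estimates of the nonzero path gamma_1 = {truth['eta_ind1->eta_dep']}: "
          f"max |estimate| = {g1.drop('CBSEM_NML').abs().max():.2e}")
    print(f"CB-SEM recovers gamma_1 = {g1['CBSEM_NML']:.6f}")
    print("No rescaling of the composites can move those zeros: the bias "
          "matrix is not diagonal (run compositebias bias for the matrix).")


if __name__ == "__main__":
    main()
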