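"""The four-model longitudinal suite and its report.

Each model regresses longitudinal eGFR on the 12 clinical terms plus
follow-up time and four structural predictors.  Mean glomerular tuft
area and the cortical density of patent glomeruli appear in every
structural model; the remaining two slots are filled by, respectively,
the pathologist descriptors (IF, TA), their morphometric analogues
(FIA, FATA), the first two principal components (PC1, PC2), or PC1 and
PC3.  A clinical-only model is fitted for comparison.  Every model is
scored by QIC and by the leave-one-subject-out predictive R^2 against
the time-only reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

from .errors import NephromorphError
from .gee import GEEResults
from .longitudinal import FitQuality, ModelSpec, fit_gee, loo_press_r2

__all__ = ["STRUCTURAL_SETS", "ModelReport", "run_model_suite", "load_suite_config"]

#: default structural-variable sets of the four models
STRUCTURAL_SETS = {
    "clinical": (),
    "model1": ("IF", "TA", "A_G_um2", "N_A_per_mm2"),
    "model2": ("FIA", "FATA", "A_G_um2", "N_A_per_mm2"),
    "model3": ("PC1", "PC2", "A_G_um2", "N_A_per_mm2"),
    "model4": ("PC1", "PC3", "A_G_um2", "N_A_per_mm2"),
}


def load_suite_config(path) -> dict:
    """Read a YAML suite config: {model name: [structural columns]}."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return {name: tuple(cols) for name, cols in config.items()}


@dataclass
class ModelReport:
    """Per-model fits, p-values, QIC and predictive R^2."""

    fits: dict[str, GEEResults]
    quality: dict[str, FitQuality]
    alpha: float = 0.05
    provenance: str = ""

    def coefficients(self, name: str) -> pd.DataFrame:
        fit = self.fits[name]
        return pd.DataFrame(
            {
                "coef": fit.params,
                "robust_se": fit.bse,
                "p": fit.pvalues,
                "significant": fit.pvalues < self.alpha,
            },
            index=fit.exog_names,
        )

    def significant_terms(self, name: str) -> list[str]:
        table = self.coefficients(name)
        return [t for t in table.index if table.loc[t, "significant"] and t != "intercept"]

    def score_table(self) -> pd.DataFrame:
        rows = {
            name: {
                "qic": q.qic,
                "press": q.press,
                "ssr": q.ssr,
                "r2_pred_pct": 100.0 * q.r2_pred,
                "n_subjects": self.fits[name].n_subjects,
            }
            for name, q in self.quality.items()
        }
        return pd.DataFrame(rows).T

    def to_markdown(self) -> str:
        """Human-readable report mirroring a per-model p-value layout."""
        lines = [f"# Longitudinal model suite ({self.provenance})", ""]
        for name, fit in self.fits.items():
            q = self.quality[name]
            lines.append(f"## {name}")
            table = self.coefficients(name)
            lines.append("")
            lines.append("| term | coef | robust SE | Pr(>\\|W\\|) |")
            lines.append("|---|---|---|---|")
            for term, row in table.iterrows():
                p = f"**{row['p']:.4g}**" if row["significant"] else f"{row['p']:.4g}"
                lines.append(
                    f"| {term} | {row['coef']:.4f} | {row['robust_se']:.4f} | {p} |"
                )
            lines.append("")
            lines.append(
                f"QIC {q.qic:.2f} | R^2_pred {100 * q.r2_pred:.1f}% | "
                f"n = {fit.n_subjects}"
            )
            lines.append("")
        return "\n".join(lines)


def run_model_suite(
    dataset,
    structural_sets: dict | None = None,
    working_correlation: str = "independence",
    alpha: float = 0.05,
    with_press: bool = True,
) -> ModelReport:
    """Fit the clinical-only model plus the four structural models.

    Fitting errors are annotated with the model id and re-raised.
    """
    sets = structural_sets or STRUCTURAL_SETS
    fits: dict[str, GEEResults] = {}
    quality: dict[str, FitQuality] = {}
    for name, structural in sets.items():
        spec = ModelSpec.clinical(
            structural=tuple(structural), name=name,
            working_correlation=working_correlation,
        )
        try:
            fits[name] = fit_gee(dataset, spec)
            if with_press:
                quality[name] = loo_press_r2(dataset, spec)
            else:
                quality[name] = FitQuality(
                    qic=fits[name].qic(), press=float("nan"),
                    ssr=float("nan"), r2_pred=float("nan"),
                )
        except NephromorphError as err:
            raise type(err)(f"[{name}] {err}") from err
    return ModelReport(
        fits=fits, quality=quality, alpha=alpha, provenance=dataset.provenance
    )
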