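"""Ecomorphological traits: body mass, dietary ratios, and the
extant-trained carnivory index.

Body mass is estimated allometrically from lower-first-molar (m1)
length: ``log10(mass_kg) = a + b * log10(m1_mm)``. The shipped default
coefficients follow published canid allometries and are non-normative
configuration — supply the coefficients of your preferred regression.

Three dietary ratios summarize the slicing/grinding balance of the
dentition and jaw robustness:

* RBL  — relative blade length: trigonid blade / total m1 length,
* RUGA — relative upper grinding area: sqrt(upper molar grinding area)
  / upper P4 length,
* JD/DL — jaw depth / dentary length.

A correlation-matrix PCA of the three ratios over an extant comparative
set of known diet yields the carnivory index (PC1, sign fixed so RBL
loads positively: carnivory increases to the right; PC2 approximates
durophagy). Fossil species are projected through the extant
standardization and loadings, then the fossil PC1 scores are re-centred
on their median. Diet-category labels are used for visualization only,
never in the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MassCoefficients",
    "DEFAULT_MASS_COEFFS",
    "estimate_body_mass",
    "compute_dietary_ratios",
    "DentaryImputer",
    "fit_dentary_imputer",
    "CarnivoryModel",
    "fit_carnivory_index",
    "project_carnivory",
    "classify_diet",
]

RATIO_COLUMNS = ["RBL", "RUGA", "JD_DL"]


@dataclass(frozen=True)
class MassCoefficients:
    """log10(mass_kg) = a + b * log10(m1_length_mm)."""

    a: float
    b: float


# Non-normative default in the style of published extant-canid m1-length
# allometries; replace with the coefficients of your chosen regression.
DEFAULT_MASS_COEFFS = MassCoefficients(a=-2.27, b=2.97)


def estimate_body_mass(m1_length, coeffs: MassCoefficients = DEFAULT_MASS_COEFFS):
    """Estimate body mass (kg) and log10 mass from m1 length (mm)."""
    m1 = np.asarray(m1_length, dtype=float)
    if np.any(m1 <= 0):
        raise ValueError("m1_length must be > 0")
    log10_mass = coeffs.a + coeffs.b * np.log10(m1)
    mass = 10.0 ** log10_mass
    if np.ndim(m1_length) == 0:
        return float(mass), float(log10_mass)
    return mass, log10_mass


@dataclass
class DentaryImputer:
    """Per-subfamily allometry log10(dentary) = a + b * log10(m1)."""

    coeffs: dict  # subfamily -> (a, b)
    n_train: dict = field(default_factory=dict)

    def predict(self, m1_length, subfamily: str) -> float:
        if subfamily not in self.coeffs:
            raise KeyError(f"no dentary model for subfamily {subfamily!r}")
        a, b = self.coeffs[subfamily]
        return float(10 ** (a + b * np.log10(m1_length)))


def fit_dentary_imputer(training: pd.DataFrame) -> DentaryImputer:
    """Least-squares log-log fit of dentary length on m1 length, one
    model per subfamily (no pooling); needs >= 3 complete rows each."""
    coeffs, ns = {}, {}
    for sf, grp in training.groupby("subfamily"):
        ok = grp.dropna(subset=["m1_length", "dentary_length"])
        if len(ok) < 3:
            continue
        x = np.log10(ok["m1_length"].to_numpy(dtype=float))
        y = np.log10(ok["dentary_length"].to_numpy(dtype=float))
        b, a = np.polyfit(x, y, 1)
        coeffs[sf] = (float(a), float(b))
        ns[sf] = len(ok)
    if not coeffs:
        raise ValueError("no subfamily with >= 3 complete training rows")
    return DentaryImputer(coeffs=coeffs, n_train=ns)


def compute_dietary_ratios(morpho: pd.DataFrame, imputer: DentaryImputer | None = None) -> pd.DataFrame:
    """RBL, RUGA and JD/DL per species; missing ratios stay missing.

    Dentary length absent + imputer supplied -> imputed (flagged);
    absent with no imputer -> JD/DL left NaN, never fabricated.
    """
    m = morpho.copy()
    for col in ["m1_length", "trigonid_blade_length", "upper_grinding_area", "p4_length", "jaw_depth"]:
        if col in m.columns and np.any(m[col].dropna() <= 0):
            raise ValueError(f"non-positive values in {col}")
    out = pd.DataFrame(index=m.index)
    out["species"] = m["species"]
    out["RBL"] = m["trigonid_blade_length"] / m["m1_length"]
    out["RUGA"] = np.sqrt(m["upper_grinding_area"]) / m["p4_length"]
    dentary = m["dentary_length"].copy() if "dentary_length" in m.columns else pd.Series(np.nan, index=m.index)
    imputed = pd.Series(False, index=m.index)
    if imputer is not None:
        for i in m.index:
            if pd.isna(dentary.loc[i]) and not pd.isna(m.loc[i, "m1_length"]):
                sf = m.loc[i, "subfamily"] if "subfamily" in m.columns else None
                if sf in imputer.coeffs:
                    dentary.loc[i] = imputer.predict(m.loc[i, "m1_length"], sf)
                    imputed.loc[i] = True
    out["JD_DL"] = m["jaw_depth"] / dentary
    out["dentary_imputed"] = imputed
    if "subfamily" in m.columns:
        out["subfamily"] = m["subfamily"]
    if "diet_category" in m.columns:
        out["diet_category"] = m["diet_category"]
    bad = out["RBL"].dropna() > 1.0 + 1e-9
    if bad.any():
        raise ValueError("trigonid blade length exceeds m1 length for some species")
    return out


@dataclass
class CarnivoryModel:
    """Correlation-matrix PCA of the three dietary ratios.

    Stores the extant training means/SDs, orthonormal loading matrix
    (columns = PCs, PC1 sign fixed so RBL loads positively), explained
    variance shares, and — once fossils have been projected — the fossil
    median used to re-centre PC1.
    """

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # 3x3, columns = components
    explained: np.ndarray  # variance shares, sum to 1
    recenter_const: float | None = None

    def transform(self, ratios: pd.DataFrame) -> pd.DataFrame:
        """Scores in the extant-standardized space (no recentring)."""
        Z = (ratios[RATIO_COLUMNS].to_numpy(dtype=float) - self.means) / self.sds
        S = Z @ self.loadings
        return pd.DataFrame(
            S, index=ratios.index, columns=[f"pc{i + 1}" for i in range(S.shape[1])]
        )

    def to_yaml(self, path) -> None:
        payload = {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained": self.explained.tolist(),
            "recenter_const": self.recenter_const,
            "ratio_order": RATIO_COLUMNS,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "CarnivoryModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained=np.asarray(d["explained"], dtype=float),
            recenter_const=d.get("recenter_const"),
        )


def fit_carnivory_index(extant_ratios: pd.DataFrame) -> CarnivoryModel:
    """Correlation-matrix PCA of (RBL, RUGA, JD/DL) over extant species.

    Standardizes each ratio by its training mean/SD (ddof=1, as in R's
    prcomp with scale.=TRUE), eigendecomposes the correlation matrix,
    and fixes the PC1 sign so that RBL loads positively.
    """
    X = extant_ratios[RATIO_COLUMNS].dropna().to_numpy(dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need >= 4 extant species with all three ratios")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 1e-12 * (np.abs(means) + 1.0)):
        raise ValueError("zero-variance ratio: correlation matrix undefined")
    Z = (X - means) / sds
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    L = evecs[:, order]
    if L[0, 0] < 0:  # RBL loads positively on PC1
        L[:, 0] = -L[:, 0]
    for j in range(1, L.shape[1]):  # deterministic sign for the rest
        jmax = np.argmax(np.abs(L[:, j]))
        if L[jmax, j] < 0:
            L[:, j] = -L[:, j]
    return CarnivoryModel(
        means=means, sds=sds, loadings=L, explained=evals / evals.sum()
    )


def project_carnivory(model: CarnivoryModel, fossil_ratios: pd.DataFrame, recenter: bool = True):
    """Project fossil ratios through the extant model.

    Species with any missing ratio are excluded (and reported). With
    ``recenter=True`` the fossil PC1 median is subtracted (and stored on
    the model) so the returned carnivory index has median exactly 0.

    Returns ``(scores, excluded)`` where scores has columns species,
    pc1, pc2 and excluded is the list of dropped species.
    """
    complete = fossil_ratios[RATIO_COLUMNS].notna().all(axis=1)
    excluded = list(fossil_ratios.loc[~complete, "species"]) if "species" in fossil_ratios else list(
        fossil_ratios.index[~complete]
    )
    sub = fossil_ratios.loc[complete]
    S = model.transform(sub)
    pc1 = S["pc1"].to_numpy()
    if recenter:
        med = float(np.median(pc1))
        model.recenter_const = med
        pc1 = pc1 - med
    scores = pd.DataFrame(
        {
            "species": sub["species"].to_numpy() if "species" in sub else sub.index,
            "pc1": pc1,
            "pc2": S["pc2"].to_numpy(),
        }
    )
    return scores, excluded


def classify_diet(percent_meat: float) -> str:
    """Diet category from percentage of vertebrate meat in the diet:
    <50% hypocarnivore, 50-70% mesocarnivore, >70% hypercarnivore."""
    if not 0.0 <= percent_meat <= 100.0:
        raise ValueError("percent_meat must be in [0, 100]")
    if percent_meat < 50.0:
        return "hypocarnivore"
    if percent_meat <= 70.0:
        return "mesocarnivore"
    return "hypercarnivore"
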