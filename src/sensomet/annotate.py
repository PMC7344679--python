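"""Putative metabolite annotation by exact-mass adduct matching.

Each molecular feature's observed m/z is compared against theoretical
adduct m/z values computed from a compound table's molecular formulas, at
a ppm tolerance (default 5 ppm). Matches are summarized into Metabolomics
Standards Initiative (MSI) confidence levels:

* level 2 — all candidates share one molecular formula;
* level 3 — several formulas, but a single compound class;
* level 4 — no candidate, or candidates spanning several classes.

Monoisotopic masses come from :mod:`pyteomics.mass` (NIST isotopic
table). Supported elements are C, H, N, O, P, S and Na; anything else in
a formula is rejected. Adduct shifts are derived from the same table at
import time, including the electron mass, rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .tables import CompoundDB, FeatureTable

SUPPORTED_ELEMENTS = frozenset({"C", "H", "N", "O", "P", "S", "Na"})

ELECTRON_MASS = 0.00054857990946  # Da

_H = _pmass.calculate_mass(formula="H")
_NA = _pmass.calculate_mass(formula="Na")
_NH4 = _pmass.calculate_mass(formula="NH4")
_ACOH = _pmass.calculate_mass(formula="C2H4O2")  # acetic acid

PROTON_MASS = _H - ELECTRON_MASS


def formula_monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of an elemental formula such as ``C15H14O6``.

    Raises
    ------
    ValueError
        For an empty or malformed formula, or one using an element outside
        the supported set (C, H, N, O, P, S, Na).
    """
    if not formula or not isinstance(formula, str):
        raise ValueError("empty or non-string formula")
    try:
        comp = _pmass.Composition(formula=formula)
    except Exception as exc:
        raise ValueError(f"malformed formula {formula!r}: {exc}") from exc
    if not comp:
        raise ValueError(f"formula {formula!r} contains no atoms")
    bad = set(comp) - SUPPORTED_ELEMENTS
    if bad:
        raise ValueError(
            f"unsupported element(s) {sorted(bad)} in formula {formula!r}; "
            f"supported: {sorted(SUPPORTED_ELEMENTS)}"
        )
    if any(n <= 0 for n in comp.values()):
        raise ValueError(f"non-positive element count in formula {formula!r}")
    return float(_pmass.calculate_mass(composition=comp))


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct: name, mode, mass shift (Da) and charge.

    ``mass_shift`` already accounts for electron gain/loss, so for a
    singly charged species m/z = neutral mass + shift.
    """

    name: str
    mode: str  # "positive" | "negative"
    mass_shift: float
    charge: int

    def __post_init__(self) -> None:
        if self.mode == "positive" and self.charge != +1:
            raise ValueError(f"positive-mode adduct {self.name} must carry charge +1")
        if self.mode == "negative" and self.charge != -1:
            raise ValueError(f"negative-mode adduct {self.name} must carry charge -1")


# Standard singly charged adducts; shifts derived from the isotopic table.
ADDUCTS: dict[str, AdductSpec] = {
    "M+H": AdductSpec("M+H", "positive", _H - ELECTRON_MASS, +1),
    "M+Na": AdductSpec("M+Na", "positive", _NA - ELECTRON_MASS, +1),
    "M+NH4": AdductSpec("M+NH4", "positive", _NH4 - ELECTRON_MASS, +1),
    "M-H": AdductSpec("M-H", "negative", -_H + ELECTRON_MASS, -1),
    "M+AcOH-H": AdductSpec("M+AcOH-H", "negative", _ACOH - _H + ELECTRON_MASS, -1),
    # intrinsic cation (e.g. flavylium anthocyanins): the molecule itself
    # minus one electron is the observed ion
    "M+": AdductSpec("M+", "positive", -ELECTRON_MASS, +1),
}

POSITIVE_NEUTRAL_ADDUCTS = ("M+H", "M+Na", "M+NH4")
NEGATIVE_NEUTRAL_ADDUCTS = ("M-H", "M+AcOH-H")


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of a singly charged adduct of a neutral mass."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if not neutral_mass > 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return neutral_mass + adduct.mass_shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million, theoretical m/z in the
    denominator."""
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Candidate:
    compound: str
    formula: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    compound_class: str


@dataclass
class AnnotationResult:
    feature_id: str
    mz: float
    candidates: list[Candidate] = field(default_factory=list)
    msi_level: int = 4


def assign_msi_level(candidates: list[Candidate]) -> int:
    """MSI confidence level implied by an exact-mass candidate set."""
    if not candidates:
        return 4
    formulas = {c.formula for c in candidates}
    if len(formulas) == 1:
        return 2
    classes = {c.compound_class for c in candidates}
    if len(classes) == 1:
        return 3
    return 4


def theoretical_ions(db: CompoundDB, mode: str) -> pd.DataFrame:
    """All (compound, adduct, theoretical m/z) ions the table can form in
    the given mode. Intrinsically charged compounds only form M+ (positive
    mode); neutral compounds form the mode's standard adducts."""
    rows = []
    for rec in db.table.itertuples(index=False):
        m = formula_monoisotopic_mass(rec.formula)
        if int(rec.intrinsic_charge) == 1:
            if mode == "positive":
                rows.append((rec.name, rec.formula, "M+", adduct_mz(m, "M+"), rec.compound_class))
            continue
        names = POSITIVE_NEUTRAL_ADDUCTS if mode == "positive" else NEGATIVE_NEUTRAL_ADDUCTS
        for a in names:
            rows.append((rec.name, rec.formula, a, adduct_mz(m, a), rec.compound_class))
    return pd.DataFrame(
        rows, columns=["compound", "formula", "adduct", "theoretical_mz", "compound_class"]
    )


def match_features(
    table: FeatureTable, db: CompoundDB, tol_ppm: float = 5.0
) -> list[AnnotationResult]:
    """Annotate every feature of ``table`` against ``db`` at ``tol_ppm``.

    Candidates within tolerance are sorted by absolute ppm error; features
    with no candidate get an empty list and MSI level 4.
    """
    ions = theoretical_ions(db, table.mode)
    theo = ions["theoretical_mz"].to_numpy()
    results: list[AnnotationResult] = []
    for fid, obs in table.mz.items():
        obs = float(obs)
        if len(theo):
            errs = (obs - theo) / theo * 1e6
            hit_idx = np.flatnonzero(np.abs(errs) <= tol_ppm)
        else:
            hit_idx = np.array([], dtype=int)
        cands = [
            Candidate(
                compound=ions.at[i, "compound"],
                formula=ions.at[i, "formula"],
                adduct=ions.at[i, "adduct"],
                theoretical_mz=float(theo[i]),
                ppm_error=float(errs[i]),
                compound_class=ions.at[i, "compound_class"],
            )
            for i in hit_idx
        ]
        cands.sort(key=lambda c: abs(c.ppm_error))
        results.append(
            AnnotationResult(
                feature_id=str(fid), mz=obs, candidates=cands, msi_level=assign_msi_level(cands)
            )
        )
    return results


def annotation_frame(results: list[AnnotationResult]) -> pd.DataFrame:
    """Flatten annotation results to one row per candidate (or one blank
    row for unannotated features)."""
    rows = []
    for r in results:
        if r.candidates:
            for c in r.candidates:
                rows.append(
                    (r.feature_id, r.mz, c.adduct, c.compound, c.formula,
                     c.compound_class, c.ppm_error, r.msi_level)
                )
        else:
            rows.append((r.feature_id, r.mz, "", "", "", "", np.nan, r.msi_level))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "mz", "adduct", "compound", "formula",
                 "compound_class", "ppm_error", "msi_level"],
    )
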