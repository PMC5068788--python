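"""Putative metabolite annotation by adduct mass arithmetic and ppm matching.

An LC-MS feature "RT_mz" observed in negative mode is compared against
[M-H]- theoretical m/z values of candidate compounds (positive mode:
[M+H]+); candidates within the ppm tolerance (default 10 ppm) are returned
sorted by absolute mass error.  Monoisotopic masses are computed from
elemental formulas (C, H, N, O, P, S) using IUPAC monoisotopic atomic
masses; the electron mass is neglected in the proton transfer, which is
well below 1 ppm at metabolite masses.

A small compound table covering typical amniotic-fluid annotations is
bundled (``load_bundled_compounds``); class-level entries without a
resolvable structure carry no formula and are skipped during matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "CompoundRecord",
    "AnnotationMatch",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "load_compound_table",
    "load_bundled_compounds",
    "match_features",
    "parse_feature_id",
]

#: IUPAC monoisotopic atomic masses (Da)
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

PROTON_MASS = 1.007276

SUPPORTED_ADDUCTS = ("[M+H]+", "[M-H]-")

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a CHNOPS elemental formula like 'C19H28O6S' into counts."""
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_RE.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unsupported element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula.strip()):
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic neutral mass (Da) of a CHNOPS formula."""
    return sum(MONOISOTOPIC_MASS[el] * k for el, k in parse_formula(formula).items())


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of [M+H]+ or [M-H]- for a neutral monoisotopic mass."""
    if adduct == "[M+H]+":
        return neutral_mass + PROTON_MASS
    if adduct == "[M-H]-":
        if neutral_mass <= PROTON_MASS:
            raise ValueError(f"neutral mass {neutral_mass} too small for [M-H]-")
        return neutral_mass - PROTON_MASS
    raise ValueError(f"unsupported adduct {adduct!r}; supported: {SUPPORTED_ADDUCTS}")


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


@dataclass(frozen=True)
class CompoundRecord:
    """A candidate compound: name, CHNOPS formula (may be empty for
    class-only records), metabolite class and optional reference fragments."""

    name: str
    formula: str
    class_label: str = ""
    reference_fragments: tuple = ()

    @property
    def has_formula(self) -> bool:
        return bool(self.formula and self.formula.strip())

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class AnnotationMatch:
    feature_id: str
    observed_mz: float
    adduct: str
    candidate: CompoundRecord = field(repr=False)
    theoretical_mz: float = 0.0
    mass_error_ppm: float = 0.0

    @property
    def name(self) -> str:
        return self.candidate.name


def load_compound_table(path_or_frame) -> list[CompoundRecord]:
    """Read a compound table CSV with columns name, formula, class, fragments
    (semicolon-separated m/z)."""
    df = (path_or_frame if isinstance(path_or_frame, pd.DataFrame)
          else pd.read_csv(path_or_frame, dtype=str).fillna(""))
    records = []
    for _, row in df.iterrows():
        frags = tuple(float(x) for x in str(row.get("fragments", "") or "").split(";") if x)
        rec = CompoundRecord(row["name"], str(row.get("formula", "") or ""),
                             str(row.get("class", "") or ""), frags)
        if rec.has_formula:
            rec.mass  # validate formula eagerly
        records.append(rec)
    return records


def load_bundled_compounds() -> list[CompoundRecord]:
    """The bundled mini compound table of amniotic-fluid annotations."""
    with resources.files("ocplsda").joinpath("data/compounds.csv").open() as fh:
        return load_compound_table(pd.read_csv(fh, dtype=str).fillna(""))


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    """Split an 'RT_mz' identifier like '5.06_197.0808' into (rt, mz)."""
    try:
        rt_s, mz_s = str(feature_id).split("_")
        return float(rt_s), float(mz_s)
    except ValueError as exc:
        raise ValueError(f"feature id {feature_id!r} is not 'RT_mz'") from exc


def match_features(features, compounds=None, tolerance_ppm: float = 10.0
                   ) -> list[AnnotationMatch]:
    """Match observed features against candidate compounds by adduct m/z.

    ``features`` is an iterable of ``(feature_id, observed_mz, mode)`` with
    mode "negative" or "positive"; negative mode tries [M-H]-, positive
    [M+H]+.  Matches within ``tolerance_ppm`` are returned sorted by
    |ppm| then candidate name.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if compounds is None:
        compounds = load_bundled_compounds()
    compounds = list(compounds)
    if not compounds:
        raise ValueError("compound table is empty")
    usable = [(c, c.mass) for c in compounds if c.has_formula]
    out: list[AnnotationMatch] = []
    for feature_id, observed_mz, mode in features:
        if mode not in ("negative", "positive"):
            raise ValueError(f"mode must be 'negative' or 'positive', got {mode!r}")
        adduct = "[M-H]-" if mode == "negative" else "[M+H]+"
        hits = []
        for comp, mass in usable:
            theo = adduct_mz(mass, adduct)
            err = ppm_error(float(observed_mz), theo)
            if abs(err) <= tolerance_ppm:
                hits.append(AnnotationMatch(str(feature_id), float(observed_mz),
                                            adduct, comp, theo, err))
        hits.sort(key=lambda h: (abs(h.mass_error_ppm), h.name))
        out.extend(hits)
    return out


def annotation_frame(matches, univariate: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate matches (RT, m/z, adduct, ppm, putative name, class,
    fragments), optionally joined with univariate AUC/Sp/Se per feature."""
    rows = []
    for m in matches:
        rt, _ = parse_feature_id(m.feature_id)
        row = {
            "feature": m.feature_id, "rt": rt, "mz": m.observed_mz,
            "adduct": m.adduct, "mass_error_ppm": m.mass_error_ppm,
            "putative_metabolite": m.name, "metabolite_class": m.candidate.class_label,
            "fragments": ";".join(str(f) for f in m.candidate.reference_fragments),
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if univariate is not None and len(df):
        cols = [c for c in ("auc", "sensitivity", "specificity") if c in univariate.columns]
        df = df.join(univariate[cols], on="feature")
    return df
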