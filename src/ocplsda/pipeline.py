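"""End-to-end orchestration: file I/O, configuration and report generation.

A run ties the stages together in the study's order: metadata confounding
screen → pretreatment → constrained fit + post-transformation → N-fold full
cross-validation and permutation test → Monte-Carlo stability selection →
univariate complement → putative annotation.  Each ionization mode's feature
table is analyzed independently against a shared metadata table.  Every
stochastic stage derives its seed from the single master seed, so a rerun
with the same configuration reproduces every number byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import annotation_frame, load_bundled_compounds, load_compound_table, \
    match_features, parse_feature_id
from .model import OCPLSDA
from .pretreat import PretreatSpec, Pretreatment
from .stability import StabilityConfig, stability_select
from .univar import univariate_scan
from .validation import confounding_screen, validation_report

__all__ = ["RunConfig", "run_pipeline", "read_feature_table", "read_metadata"]

log = logging.getLogger("ocplsda")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path, features_in_rows: bool = False) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    if features_in_rows:
        df = df.T
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate sample id(s) in {path}: {dup}")
    return df


def read_feature_table(path, features_in_rows: bool = False) -> pd.DataFrame:
    """Read a samples × RT_mass CSV/TSV intensity table.

    Sample ids are in the first column (or first row with
    ``features_in_rows``); feature ids are preserved verbatim.
    """
    df = _read_table(path, features_in_rows)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric intensities in {path}: {exc}") from exc
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata table (class label + covariates)."""
    return _read_table(path)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of an end-to-end run; defaults follow the standard
    analysis recipe (500 permutations, 200 subsets at 0.70, top-50, >90%,
    q < 20%, folds 6/7/8)."""

    feature_tables: dict            # mode name -> path
    metadata: str
    class_col: str = "group"
    case_label: str | None = None
    constraints: list = field(default_factory=list)
    pretreat: dict = field(default_factory=dict)      # PretreatSpec kwargs
    n_components: int | str = 3
    fold_counts: tuple = (6, 7, 8)
    perm_folds: int = 7
    n_permutations: int = 500
    stability: dict = field(default_factory=dict)     # StabilityConfig kwargs
    q_threshold: float = 0.20
    tolerance_ppm: float = 10.0
    compound_table: str | None = None
    features_in_rows: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "fold_counts" in raw:
            raw["fold_counts"] = tuple(raw["fold_counts"])
        return cls(**raw)

    def pretreat_spec(self) -> PretreatSpec:
        return PretreatSpec(**self.pretreat)

    def stability_config(self, seed: int) -> StabilityConfig:
        kw = dict(self.stability)
        kw.setdefault("seed", seed)
        return StabilityConfig(**kw)


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _validate_config(cfg: RunConfig, meta: pd.DataFrame) -> None:
    if cfg.class_col not in meta.columns:
        raise KeyError(f"class column {cfg.class_col!r} not in metadata")
    missing = [c for c in cfg.constraints if c not in meta.columns]
    if missing:
        raise KeyError(f"constraint covariate(s) not in metadata: {missing}")
    counts = meta[cfg.class_col].value_counts()
    if len(counts) != 2:
        raise ValueError(f"exactly two classes required, got {list(counts.index)}")
    if counts.min() < 3:
        raise ValueError(f"fewer than 3 samples in class {counts.idxmin()!r}")


def _analyze_mode(mode: str, table: pd.DataFrame, meta: pd.DataFrame,
                  cfg: RunConfig, seeds: list[int], outdir: Path) -> dict:
    labels = meta.loc[table.index, cfg.class_col]
    cons = meta.loc[table.index, cfg.constraints] if cfg.constraints else None
    n_comp = None if cfg.n_components == "auto" else int(cfg.n_components)
    model = OCPLSDA(table, labels, constraints=cons, n_components=n_comp,
                    pretreatment=cfg.pretreat_spec(), case_label=cfg.case_label)
    res = model.fit()
    log.info("[%s] fitted: %s", mode, res.summary().replace("\n", " | "))

    report = validation_report(
        table, labels, res.latent.n_components, cons,
        fold_counts=cfg.fold_counts, n_permutations=cfg.n_permutations,
        perm_folds=cfg.perm_folds, seed=seeds[0],
        pretreatment=cfg.pretreat_spec(), case_label=cfg.case_label)

    stab = stability_select(
        table, labels, res.latent.n_components, cons,
        config=cfg.stability_config(seeds[1]),
        pretreatment=cfg.pretreat_spec(), case_label=cfg.case_label)

    Xt = pd.DataFrame(Pretreatment(cfg.pretreat_spec()).fit_transform(table),
                      index=table.index, columns=table.columns)
    uni = univariate_scan(Xt, labels, q_threshold=cfg.q_threshold,
                          case_label=cfg.case_label)

    interest = list(dict.fromkeys(list(stab.panel) +
                                  uni.index[uni["significant"]].tolist()))
    feats = []
    for fid in interest:
        try:
            _, mz = parse_feature_id(fid)
        except ValueError:
            continue
        feats.append((fid, mz, mode))
    compounds = (load_compound_table(cfg.compound_table) if cfg.compound_table
                 else load_bundled_compounds())
    matches = match_features(feats, compounds, cfg.tolerance_ppm) if feats else []
    ann = annotation_frame(matches, uni)

    stab.frequencies_frame().to_csv(outdir / f"frequencies_{mode}.csv", index=False)
    uni.to_csv(outdir / f"univariate_{mode}.csv")
    ann.to_csv(outdir / f"annotations_{mode}.csv", index=False)
    pd.DataFrame(report.roc.curve, columns=["fpr", "tpr"]).to_csv(
        outdir / f"roc_curve_{mode}.csv", index=False)
    res.save(outdir / f"model_{mode}.json")

    return {
        "n_samples": int(table.shape[0]),
        "n_features": int(table.shape[1]),
        "components": f"{res.n_pred}+{res.n_orth}",
        "validation": report.to_dict(),
        "stability": stab.to_dict(),
        "n_panel": len(stab.panel),
        "n_univariate_significant": int(uni["significant"].sum()),
        "n_annotated": int(len(ann)),
    }


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full analysis and write the run directory.

    Outputs: ``report.json`` plus per-mode frequency, univariate, annotation
    and ROC-curve CSVs, a serialized model, and ``log.txt``.  Deterministic
    given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        meta = read_metadata(config.metadata)
        _validate_config(config, meta)
        tables = {m: read_feature_table(p, config.features_in_rows)
                  for m, p in config.feature_tables.items()}
        for mode, tbl in tables.items():
            missing = tbl.index.difference(meta.index)
            if len(missing):
                raise ValueError(
                    f"sample id(s) in {mode} table but not metadata: {list(missing)[:5]}")

        screen_cols = [c for c in meta.columns if c != config.class_col]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            some_index = next(iter(tables.values())).index
            screen = confounding_screen(meta.loc[some_index, screen_cols],
                                        meta.loc[some_index, config.class_col],
                                        seed=_child_seeds(config.seed, 1)[0])
        log.info("confounding screen: metadata Q2 = %.3f -> %s", screen.metadata_q2,
                 "confounded" if screen.confounded else "no confounding")

        seeds = _child_seeds(config.seed, 2 * len(tables) + 1)[1:]
        report = {
            "seed": config.seed,
            "confounding_screen": {
                "confounded": screen.confounded,
                "metadata_q2": screen.metadata_q2,
                "per_pc_pvalues": [float(x) for x in screen.per_pc_pvalues],
            },
            "modes": {},
        }
        for i, (mode, tbl) in enumerate(tables.items()):
            report["modes"][mode] = _analyze_mode(
                mode, tbl, meta, config, seeds[2 * i:2 * i + 2], outdir)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=1)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
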