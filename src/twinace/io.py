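"""File formats, reports and the end-to-end analysis pipeline.

Pair tables are delimited text with one row per twin pair and header-named
columns ``pair_id, zygosity, sex1, sex2, phen3_1, phen7_1, phen3_2,
phen7_2[, prs1, prs2]``; phenotypes are coded 0/1/NA, zygosity is
MZ/DZSS/DZOS.  Reports are pydantic models serialized to JSON (full
precision) with a text rendering rounded to three decimals; the JSON
schema ships with the package as ``report_schema.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel

from .cholesky import FitResult, ModelSpec, fit_ml
from .inference import LRTResult, prs_tests, sex_limitation_test
from .liability import TwoByTwoTable, tetrachoric_ml
from .simulate import SimulationConfig, TwinPairRecord, simulate_pairs

logger = logging.getLogger("twinace")

__all__ = [
    "COLUMNS",
    "MODEL_REGISTRY",
    "read_pairs",
    "write_pairs",
    "AnalysisReport",
    "run_pipeline",
    "render_text",
    "report_schema",
]

COLUMNS = ["pair_id", "zygosity", "sex1", "sex2",
           "phen3_1", "phen7_1", "phen3_2", "phen7_2", "prs1", "prs2"]

#: Named structural model variants selectable in configs and the CLI.
MODEL_REGISTRY: dict[str, ModelSpec] = {
    "ACE": ModelSpec(c3=True, c7=True),
    "ACE-C3": ModelSpec(c3=True, c7=False),  # C at age 3 only
    "AE": ModelSpec(c3=False, c7=False),
    "E": ModelSpec(a=False, c3=False, c7=False),
}


# ---------------------------------------------------------------------------
# pair tables
# ---------------------------------------------------------------------------

def _parse_phen(value: str) -> int | None:
    if value in ("", "NA", "NaN", "nan"):
        return None
    if value in ("0", "1"):
        return int(value)
    if value in ("0.0", "1.0"):
        return int(float(value))
    raise ValueError(f"unparseable phenotype value {value!r}")


def _parse_prs(value: str) -> float | None:
    if value in ("", "NA", "NaN", "nan"):
        return None
    return float(value)


def read_pairs(path: str | Path) -> list[TwinPairRecord]:
    """Read and validate a wide-format pair table.

    Rows failing validation (unknown zygosity or sex codes, MZ sex
    mismatch, unparseable phenotypes) are rejected with line-numbered log
    messages; a count of dropped rows is logged.  A missing or malformed
    header raises.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = COLUMNS[:8]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    has_prs = "prs1" in df.columns and "prs2" in df.columns
    records: list[TwinPairRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            d = dict(zip(df.columns, row))
            zyg = d["zygosity"].strip()
            if zyg not in ("MZ", "DZSS", "DZOS"):
                raise ValueError(f"unknown zygosity code {zyg!r}")
            sex1, sex2 = d["sex1"].strip(), d["sex2"].strip()
            for s in (sex1, sex2):
                if s not in ("M", "F"):
                    raise ValueError(f"unknown sex code {s!r}")
            if zyg == "MZ" and sex1 != sex2:
                raise ValueError("MZ pair with mismatched sexes")
            if zyg == "DZOS" and sex1 == sex2:
                raise ValueError("DZOS pair with matching sexes")
            records.append(TwinPairRecord(
                pair_id=d["pair_id"],
                zygosity=zyg, sex1=sex1, sex2=sex2,
                phen3_1=_parse_phen(d["phen3_1"]),
                phen7_1=_parse_phen(d["phen7_1"]),
                phen3_2=_parse_phen(d["phen3_2"]),
                phen7_2=_parse_phen(d["phen7_2"]),
                prs1=_parse_prs(d["prs1"]) if has_prs else None,
                prs2=_parse_prs(d["prs2"]) if has_prs else None,
            ))
        except (ValueError, KeyError) as exc:
            n_rejected += 1
            logger.warning("%s line %d: rejected row (%s)", path, line, exc)
    if n_rejected:
        logger.warning("%s: rejected %d of %d rows", path, n_rejected, len(df))
    return records


def write_pairs(records: Sequence[TwinPairRecord], path: str | Path) -> None:
    """Write records as CSV; missing values become ``NA``; PRS values are
    written with full round-tripping precision."""

    def fmt(v) -> str:
        return "NA" if v is None else str(v)

    rows = [
        {
            "pair_id": r.pair_id, "zygosity": r.zygosity,
            "sex1": r.sex1, "sex2": r.sex2,
            "phen3_1": fmt(r.phen3_1), "phen7_1": fmt(r.phen7_1),
            "phen3_2": fmt(r.phen3_2), "phen7_2": fmt(r.phen7_2),
            "prs1": fmt(r.prs1), "prs2": fmt(r.prs2),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report model
# ---------------------------------------------------------------------------

class TetrachoricEntry(BaseModel):
    group: str
    age: int
    rho: float
    se: float | None = None
    n_pairs: int
    boundary: bool = False


class ComponentsEntry(BaseModel):
    age: int
    a: float
    c: float
    e: float
    prs: float = 0.0


class StabilityEntry(BaseModel):
    contribution_a: float
    contribution_c: float
    contribution_e: float
    contribution_prs: float
    r_liability: float
    r_a: float | None = None
    r_e: float | None = None
    proportion_a: float | None = None
    proportion_c: float | None = None
    proportion_e: float | None = None
    proportion_prs: float | None = None


class FitEntry(BaseModel):
    model_name: str
    loglik: float
    n_free: int
    converged: bool
    grad_norm: float
    params: dict[str, float]
    components: list[ComponentsEntry]
    stability: StabilityEntry | None = None
    n_pairs: int
    n_dropped: int


class TestEntry(BaseModel):
    name: str
    statistic: float
    df: int
    p_value: float
    p_value_mixture: float | None = None
    boundary: bool = False


class RunMeta(BaseModel):
    seed: int | None = None
    package_version: str
    config: dict
    config_hash: str


class AnalysisReport(BaseModel):
    """Machine-readable analysis output; every number is recomputable from
    the serialized fit entries."""

    meta: RunMeta
    tetrachoric: list[TetrachoricEntry]
    fits: list[FitEntry]
    tests: list[TestEntry]


def report_schema() -> dict:
    """The JSON schema the report validates against (shipped as
    ``report_schema.json``)."""
    return AnalysisReport.model_json_schema()


def _fit_entry(name: str, fit: FitResult) -> FitEntry:
    p = fit.params
    params = {k: getattr(p, k) for k in (
        "a11", "a21", "a22", "c11", "c21", "c22", "e11", "e21", "e22",
        "b3", "b7", "beta_sex3", "beta_sex7", "tau3", "tau7")}
    if fit.r_os is not None:
        params["r_os"] = fit.r_os
    vc = fit.variance_components
    components = [ComponentsEntry(age=3, a=vc.age3.a, c=vc.age3.c,
                                  e=vc.age3.e, prs=vc.age3.prs)]
    if vc.age7 is not None and fit.model.bivariate:
        components.append(ComponentsEntry(age=7, a=vc.age7.a, c=vc.age7.c,
                                          e=vc.age7.e, prs=vc.age7.prs))
    stability = None
    if fit.model.bivariate:
        s = fit.stability
        stability = StabilityEntry(
            contribution_a=s.contribution_a, contribution_c=s.contribution_c,
            contribution_e=s.contribution_e, contribution_prs=s.contribution_prs,
            r_liability=s.r_liability, r_a=s.r_a, r_e=s.r_e,
            proportion_a=s.proportion_a, proportion_c=s.proportion_c,
            proportion_e=s.proportion_e, proportion_prs=s.proportion_prs,
        )
    return FitEntry(
        model_name=name, loglik=fit.loglik, n_free=fit.n_free,
        converged=fit.converged, grad_norm=fit.grad_norm, params=params,
        components=components, stability=stability,
        n_pairs=fit.n_pairs, n_dropped=fit.n_dropped,
    )


def _tetrachoric_entries(records) -> list[TetrachoricEntry]:
    entries = []
    pooled = {"MZ": [], "DZ-SS": [], "DZ-OS": []}
    for rec in records:
        key = {"MZ": "MZ", "DZSS": "DZ-SS", "DZOS": "DZ-OS"}[rec.zygosity.upper()]
        pooled[key].append(rec)
    for group, recs in pooled.items():
        for age in (3, 7):
            xs, ys = [], []
            for rec in recs:
                p1, p2 = ((rec.phen3_1, rec.phen3_2) if age == 3
                          else (rec.phen7_1, rec.phen7_2))
                if p1 is not None and p2 is not None:
                    xs.append(p1)
                    ys.append(p2)
            if not xs:
                continue
            try:
                fit = tetrachoric_ml(TwoByTwoTable.from_pairs(xs, ys))
            except ValueError as exc:
                logger.warning("tetrachoric %s age %d skipped: %s", group, age, exc)
                continue
            entries.append(TetrachoricEntry(
                group=group, age=age, rho=fit.rho, se=fit.se,
                n_pairs=len(xs), boundary=fit.boundary,
            ))
    # raw within-person cross-age correlation (unadjusted counterpart of the
    # model-based liability correlation); age field 0 marks "ages 3-7"
    xs, ys = [], []
    for rec in records:
        for p3, p7 in ((rec.phen3_1, rec.phen7_1), (rec.phen3_2, rec.phen7_2)):
            if p3 is not None and p7 is not None:
                xs.append(p3)
                ys.append(p7)
    if xs:
        try:
            fit = tetrachoric_ml(TwoByTwoTable.from_pairs(xs, ys))
            entries.append(TetrachoricEntry(
                group="within-person-3-7", age=0, rho=fit.rho, se=fit.se,
                n_pairs=len(xs), boundary=fit.boundary,
            ))
        except ValueError as exc:
            logger.warning("cross-age tetrachoric skipped: %s", exc)
    return entries


def _lrt_entry(name: str, lrt: LRTResult) -> TestEntry:
    return TestEntry(name=name, statistic=lrt.statistic, df=lrt.df,
                     p_value=lrt.p_value, p_value_mixture=lrt.p_value_mixture,
                     boundary=lrt.boundary_flag)


def run_pipeline(
    data: str | Path | Sequence[TwinPairRecord] | None = None,
    sim_config: SimulationConfig | None = None,
    models: Sequence[str] = ("ACE-C3",),
    tests: Sequence[str] = ("sex",),
    seed: int | None = None,
    points: int = 1024,
) -> AnalysisReport:
    """End-to-end analysis: tetrachoric correlations per group, ML model
    fits, configured tests, and a validated report.

    ``data`` is a pair-table path or a record sequence; alternatively a
    `SimulationConfig` generates the cohort.  Deterministic for a fixed
    seed/config.
    """
    config: dict = {"models": list(models), "tests": list(tests),
                    "points": points, "seed": seed}
    if data is None and sim_config is None:
        raise ValueError("either data or sim_config must be provided")
    if data is None:
        if seed is not None:
            sim_config = SimulationConfig(**{**sim_config.__dict__, "seed": seed})
        records = simulate_pairs(sim_config)
        config["simulate"] = {k: v for k, v in sim_config.__dict__.items()
                              if k != "params"}
    elif isinstance(data, (str, Path)):
        records = read_pairs(data)
        config["data"] = str(data)
    else:
        records = list(data)
        config["data"] = "<records>"
    if not records:
        raise ValueError("empty dataset: no valid pair records")

    fits: list[FitEntry] = []
    test_entries: list[TestEntry] = []
    for name in models:
        if name not in MODEL_REGISTRY:
            raise ValueError(f"unknown model {name!r}; choose from "
                             f"{sorted(MODEL_REGISTRY)}")
        fit = fit_ml(records, MODEL_REGISTRY[name], seed=seed or 0, points=points)
        fits.append(_fit_entry(name, fit))

    if "sex" in tests:
        report = sex_limitation_test(records)
        for age, lrt in report.mz_tests.items():
            test_entries.append(_lrt_entry(f"sex-equality-MZ-age{age}", lrt))
        for age, lrt in report.dz_tests.items():
            test_entries.append(_lrt_entry(f"sex-equality-DZ-age{age}", lrt))
    if "prs" in tests:
        prs = prs_tests(records, MODEL_REGISTRY[models[0]], seed=seed or 0,
                        points=points)
        test_entries.append(_lrt_entry("prs-equal-slopes", prs.equal_slopes))
        test_entries.append(_lrt_entry("prs-zero-slope", prs.zero_slope))

    try:
        version = metadata.version("twinace")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    meta = RunMeta(seed=seed, package_version=version, config=config,
                   config_hash=hashlib.sha256(blob).hexdigest()[:16])
    return AnalysisReport(meta=meta, tetrachoric=_tetrachoric_entries(records),
                          fits=fits, tests=test_entries)


def render_text(report: AnalysisReport) -> str:
    """Human-readable rendering, three decimals throughout."""

    def f3(v) -> str:
        return "   NA" if v is None else f"{v:5.3f}"

    lines = ["Twin liability analysis", "=" * 46, ""]
    lines.append("Tetrachoric correlations (cross-twin)")
    for e in report.tetrachoric:
        se = f" (se {e.se:.3f})" if e.se is not None else ""
        label = f"age {e.age}" if e.age else "ages 3-7"
        lines.append(f"  {e.group:6s} {label}: rho {f3(e.rho)}{se}  "
                     f"[n={e.n_pairs}]")
    for fit in report.fits:
        lines.append("")
        lines.append(f"Model {fit.model_name}: loglik {fit.loglik:.3f}, "
                     f"{fit.n_free} free parameters, "
                     f"{'converged' if fit.converged else 'NOT converged'}")
        lines.append("  Standardized liability variance components")
        for c in fit.components:
            lines.append(f"    age {c.age}: A {f3(c.a)}  C {f3(c.c)}  "
                         f"E {f3(c.e)}  PRS {f3(c.prs)}")
        if fit.stability is not None:
            s = fit.stability
            lines.append(f"  Liability covariance ages 3-7: {f3(s.r_liability)}"
                         f"  (rA {f3(s.r_a)}, rE {f3(s.r_e)})")
            lines.append(f"    contributions  A {f3(s.contribution_a)}  "
                         f"C {f3(s.contribution_c)}  E {f3(s.contribution_e)}")
            lines.append(f"    proportions    A {f3(s.proportion_a)}  "
                         f"C {f3(s.proportion_c)}  E {f3(s.proportion_e)}")
    if report.tests:
        lines.append("")
        lines.append("Tests")
        for t in report.tests:
            mix = (f", mixture p {t.p_value_mixture:.3f}"
                   if t.p_value_mixture is not None else "")
            lines.append(f"  {t.name}: chi2({t.df}) = {t.statistic:.3f}, "
                         f"p = {t.p_value:.3f}{mix}")
    lines.append("")
    lines.append(f"seed={report.meta.seed}  config_hash={report.meta.config_hash}  "
                 f"twinace {report.meta.package_version}")
    return "\n".join(lines)
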