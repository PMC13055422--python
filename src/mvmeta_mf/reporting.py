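"""End-to-end pipeline: load -> filter -> univariate -> MVMA fits -> report.

Runs the whole evidence-synthesis workflow on one effect table and
collects machine-readable outputs: per-factor univariate pooling, a
publication-style posterior summary table for each requested model
variant, the between-study correlation matrix, forest-plot data,
and the adjusted-vs-unadjusted odds-ratio comparison for a designated
primary factor (anterior commissure involvement by default).
"""

from __future__ import annotations

import json
import platform
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datasets import builtin_table1
from .effect_table import EffectTable, filter_factors_min_studies, load_effect_table, reporting_counts
from .mvma import (
    MvmaConfig,
    PosteriorSummary,
    exponentiate_summary,
    fit_mvma,
    full_profile,
    test_profile,
)
from .univariate import forest_data, pool_table

__all__ = [
    "PipelineError",
    "AdjustedOrReport",
    "PipelineReport",
    "significance_classification",
    "consistently_significant",
    "run_pipeline",
    "read_report",
]

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def significance_classification(cri_lo: float, cri_hi: float) -> str:
    """Classify one credible interval on the log-OR scale.

    ``"significant"`` iff the 95% interval excludes zero strictly; an
    interval touching zero exactly is classified ``"not significant"``
    (conservative closed-interval convention).
    """
    if not (np.isfinite(cri_lo) and np.isfinite(cri_hi)):
        raise ValueError("credible interval bounds must be finite")
    if cri_lo > cri_hi:
        raise ValueError(f"lower bound {cri_lo} exceeds upper bound {cri_hi}")
    return "significant" if (cri_lo > 0.0 or cri_hi < 0.0) else "not significant"


def consistently_significant(fits: Mapping[str, PosteriorSummary]) -> set[str]:
    """Factors whose 95% CrI excludes zero under *every* fitted model."""
    if not fits:
        return set()
    out: set[str] | None = None
    for fit in fits.values():
        sig = {
            fid
            for fid in fit.summary.index
            if significance_classification(*fit.cri95(fid)) == "significant"
        }
        out = sig if out is None else out & sig
    return out or set()


@dataclass(frozen=True)
class AdjustedOrReport:
    """Adjusted (multivariate) vs unadjusted (univariate) ORs for one factor.

    ``adjusted`` maps each model variant to an (OR, (lo, hi)) pair or to
    None when the variant was skipped; ``attenuation`` is the ratio of
    adjusted to unadjusted log OR per fitted variant.
    """

    factor_id: str
    univariate_or: float
    univariate_ci95: tuple[float, float]
    adjusted: Mapping[str, tuple[float, tuple[float, float]] | None]
    attenuation: Mapping[str, float | None]

    def __post_init__(self) -> None:
        if self.univariate_or <= 0:
            raise ValueError("odds ratios must be positive")
        for variant, entry in self.adjusted.items():
            if entry is not None and entry[0] <= 0:
                raise ValueError(f"adjusted OR for model {variant} must be positive")


@dataclass
class PipelineReport:
    """Everything one pipeline run produced, plus its provenance."""

    table_counts: pd.Series
    univariate: pd.DataFrame
    fits: dict[str, PosteriorSummary]
    skipped_models: tuple[str, ...]
    classification: pd.DataFrame
    consistent_significant: tuple[str, ...]
    adjusted_or: AdjustedOrReport
    forest_primary: pd.DataFrame
    meta: dict

    def to_dict(self) -> dict:
        """Full-precision, JSON-serializable payload (stable schema)."""
        fits = {}
        for variant, fit in self.fits.items():
            fits[variant] = {
                "summary": {
                    fid: {
                        "median": float(fit.summary.loc[fid, "median"]),
                        "cri_lo": float(fit.summary.loc[fid, "cri_lo"]),
                        "cri_hi": float(fit.summary.loc[fid, "cri_hi"]),
                        "tau_median": float(fit.summary.loc[fid, "tau_median"]),
                    }
                    for fid in fit.summary.index
                },
                "rho_w": fit.rho_w_summary,
                "converged": fit.converged,
                "runtime_s": fit.runtime_s,
                "engine": fit.engine,
            }
        return {
            "schema_version": SCHEMA_VERSION,
            "meta": self.meta,
            "reporting_counts": {k: int(v) for k, v in self.table_counts.items()},
            "univariate": json.loads(self.univariate.to_json(orient="index")),
            "models": fits,
            "skipped_models": list(self.skipped_models),
            "classification": json.loads(self.classification.to_json(orient="index")),
            "consistent_significant": list(self.consistent_significant),
            "adjusted_or": {
                "factor": self.adjusted_or.factor_id,
                "univariate_or": self.adjusted_or.univariate_or,
                "univariate_ci95": list(self.adjusted_or.univariate_ci95),
                "adjusted": {
                    k: None if v is None else [v[0], list(v[1])]
                    for k, v in self.adjusted_or.adjusted.items()
                },
                "attenuation": dict(self.adjusted_or.attenuation),
            },
        }

    def table2_like(self) -> pd.DataFrame:
        """Factor x model frame of 'median (lo to hi)' strings, 2 dp."""
        cols: dict[str, list[str]] = {}
        some_fit = next(iter(self.fits.values()))
        fids = list(some_fit.summary.index)
        for variant in ("H", "M0", "U"):
            if variant not in self.fits:
                continue
            fit = self.fits[variant]
            cols[f"Model {variant}"] = [
                f"{fit.summary.loc[f, 'median']:.2f} "
                f"({fit.summary.loc[f, 'cri_lo']:.2f} to {fit.summary.loc[f, 'cri_hi']:.2f})"
                for f in fids
            ]
        out = pd.DataFrame(cols, index=pd.Index(fids, name="factor"))
        out.insert(0, "n_studies", [int(self.table_counts[f]) for f in fids])
        return out

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write report.json, table2_like.csv, correlation and forest CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = out / "report.json"
        p.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        paths["report"] = p
        p = out / "table2_like.csv"
        self.table2_like().to_csv(p)
        paths["table2"] = p
        for variant, fit in self.fits.items():
            if fit.correlation is not None:
                p = out / f"correlations_{variant}.csv"
                fit.correlation.to_csv(p)
                paths[f"correlations_{variant}"] = p
        p = out / f"forest_{self.adjusted_or.factor_id}.csv"
        self.forest_primary.to_csv(p, index=False)
        paths["forest"] = p
        return paths


def read_report(path: str | Path) -> dict:
    """Read back a report.json written by :meth:`PipelineReport.write`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise PipelineError(
            f"stage read: unsupported report schema {payload.get('schema_version')!r}"
        )
    return payload


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    table: EffectTable | str | Path | None = None,
    *,
    models: Sequence[str] = ("H", "M0", "U"),
    profile: str | MvmaConfig = "full",
    primary_factor: str = "aci",
    min_studies: int = 2,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full evidence-synthesis pipeline on one effect table.

    Parameters
    ----------
    table : an EffectTable, a path to a long-layout CSV, or None for the
        built-in early glottic carcinoma dataset.
    models : subset of {"H", "M0", "U"}; omitted variants are recorded as
        skipped rather than silently absent.
    profile : "full" (published protocol), "test" (3 x 2000/2000), or an
        MvmaConfig used as template (its variant/seed are overridden).
    seed : master seed; per-model seeds are derived from it, so two runs
        with the same seed and profile produce identical numeric payloads.
    """
    t_start = time.perf_counter()
    with _stage("load"):
        if table is None:
            table = builtin_table1()
        elif not isinstance(table, EffectTable):
            table = load_effect_table(table, layout="long")
    with _stage("filter"):
        filtered = filter_factors_min_studies(table, min_studies)
        counts = reporting_counts(filtered)
        if primary_factor not in filtered.factor_ids:
            raise ValueError(
                f"primary factor {primary_factor!r} absent after filtering"
            )
    with _stage("univariate"):
        univariate = pool_table(filtered)
        forest = forest_data(filtered, primary_factor)

    bad = [m for m in models if m not in ("H", "M0", "U")]
    if bad:
        raise PipelineError(f"stage 'configure' failed: unknown models {bad}")
    if isinstance(profile, MvmaConfig):
        base = profile
    elif profile == "full":
        base = full_profile()
    elif profile == "test":
        base = test_profile()
    else:
        raise PipelineError(f"stage 'configure' failed: unknown profile {profile!r}")

    model_seeds = {
        m: int(s.generate_state(1)[0] % (2**31 - 1))
        for m, s in zip(("H", "M0", "U"), np.random.SeedSequence(seed).spawn(3))
    }
    fits: dict[str, PosteriorSummary] = {}
    from dataclasses import replace as _replace

    for variant in ("H", "M0", "U"):
        if variant not in models:
            continue
        with _stage(f"fit-{variant}"):
            cfg = _replace(base, variant=variant, seed=model_seeds[variant])
            fits[variant] = fit_mvma(filtered, cfg)
    skipped = tuple(v for v in ("H", "M0", "U") if v not in models)

    with _stage("classify"):
        rows = []
        for fid in filtered.factor_ids:
            row: dict[str, object] = {"factor": fid}
            for variant, fit in fits.items():
                row[f"model_{variant}"] = significance_classification(*fit.cri95(fid))
            rows.append(row)
        classification = pd.DataFrame(rows).set_index("factor")
        consistent = tuple(
            fid
            for fid in filtered.factor_ids
            if fid in consistently_significant(fits)
        )

    with _stage("compare"):
        uni = univariate.loc[primary_factor]
        adjusted: dict[str, tuple[float, tuple[float, float]] | None] = {}
        attenuation: dict[str, float | None] = {}
        for variant in ("H", "M0", "U"):
            if variant in fits:
                est = exponentiate_summary(fits[variant], primary_factor)
                adjusted[variant] = (est.or_point, est.or_ci95)
                attenuation[variant] = (
                    est.log_or_median / float(uni["mu_hat"])
                    if uni["mu_hat"] != 0
                    else None
                )
            else:
                adjusted[variant] = None
                attenuation[variant] = None
        adj_report = AdjustedOrReport(
            factor_id=primary_factor,
            univariate_or=float(np.exp(uni["mu_hat"])),
            univariate_ci95=(float(np.exp(uni["ci_lo"])), float(np.exp(uni["ci_hi"]))),
            adjusted=adjusted,
            attenuation=attenuation,
        )

    meta = {
        "seed": seed,
        "model_seeds": model_seeds,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "profile": {
            "chains": base.chains,
            "burn_in": base.burn_in,
            "draws": base.draws,
            "thin": base.thin,
        },
        "primary_factor": primary_factor,
        "min_studies": min_studies,
        "converged": {v: fits[v].converged for v in fits},
        "runtime_s": time.perf_counter() - t_start,
    }
    report = PipelineReport(
        table_counts=counts,
        univariate=univariate,
        fits=fits,
        skipped_models=skipped,
        classification=classification,
        consistent_significant=consistent,
        adjusted_or=adj_report,
        forest_primary=forest,
        meta=meta,
    )
    if out_dir is not None:
        with _stage("write"):
            report.write(out_dir)
    return report
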