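"""End-to-end orchestration: registry comparison, adjusted life-table
series, survey estimates, and report formatting.

``run_pipeline`` binds the stages together for one analysis: death
distribution methods per sex -> completeness tables -> rates adjusted by
the min/mean/max completeness -> abridged life tables -> 35q15 and the
female-minus-male e15 gap, plus the survey estimators and the two-source
registry comparison when those inputs are supplied. All outputs are CSV
and JSON with the configuration, seeds and decision flags recorded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .ddm import DDMModel
from .grids import FEMALE, MALE
from .lifetable import build_life_table, prob_15_50, sexgap_e15
from . import io as _io

__all__ = [
    "compare_registries",
    "format_estimate",
    "AnalysisConfig",
    "run_pipeline",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the display convention for tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compare_registries(series_a: pd.DataFrame,
                       series_b: pd.DataFrame) -> pd.DataFrame:
    """Percent difference of registry B relative to registry A by year/sex.

    Inputs are tidy frames with columns ``year,sex,count``. Output rows
    carry ``count_a``, ``count_b``, the full-precision ``pct_diff``
    (``100 * (count_b/count_a - 1)``) and its one-decimal half-up display
    value ``pct_diff_display``; rows with ``count_a == 0`` are flagged
    undefined.
    """
    a = series_a.rename(columns={"count": "count_a"})
    b = series_b.rename(columns={"count": "count_b"})
    merged = a.merge(b, on=["year", "sex"], how="inner", validate="1:1")
    if len(merged) == 0:
        raise ValueError("no matching (year, sex) keys between the series")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (merged["count_b"] / merged["count_a"] - 1.0)
    merged["pct_diff"] = np.where(merged["count_a"] > 0, pct, np.nan)
    merged["defined"] = merged["count_a"] > 0
    merged["pct_diff_display"] = [
        round_half_up(v, 1) if np.isfinite(v) else np.nan
        for v in merged["pct_diff"]
    ]
    return merged


def format_estimate(mean: float, min_: float, max_: float) -> str:
    """Render ``mean (min-max)`` with two decimals and an en-dash."""
    if not (min_ <= mean <= max_):
        raise ValueError(
            f"ordering violated: min={min_!r}, mean={mean!r}, max={max_!r}"
        )
    return f"{mean:.2f} ({min_:.2f}–{max_:.2f})"


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class AnalysisConfig:
    """File paths and tuning parameters for one pipeline run."""

    census_file: str
    deaths_file: str
    out_dir: str
    sibling_file: str | None = None
    household_file: str | None = None
    registry_file_a: str | None = None
    registry_file_b: str | None = None
    reference_files: tuple = ()
    sexes: tuple = (FEMALE, MALE)
    methods: tuple = ("seg", "ggbseg")
    min_age: int = 15
    high_end: int = 80
    min_groups: int = 8
    fit: str = "ols"
    open_closure_e: float | None = None
    sibling_period: tuple | None = None
    bootstrap_reps: int = 200
    household_window: float = 5.0
    seed: int = 0
    radix: float = 100_000.0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(path, what):
    if path is None:
        return None
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Returns the report bundle as a dict of DataFrames/values and writes
    everything under ``config.out_dir``. Any stage failure raises with
    the stage name prepended.
    """
    census_path = _require(config.census_file, "census")
    deaths_path = _require(config.deaths_file, "deaths")
    for opt, what in [
        (config.sibling_file, "sibling survey"),
        (config.household_file, "household survey"),
        (config.registry_file_a, "registry A"),
        (config.registry_file_b, "registry B"),
    ]:
        _require(opt, what)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    bundle: dict = {}
    meta = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "decisions": {
            "a_closed_intervals": "n/2",
            "open_interval_closure": "e = 1/M(open)",
            "ggb_fit": config.fit,
            "ggbseg_adjusts": "census 2",
            "date_imputation_offset": 0.5,
        },
        "log": [],
    }

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    census = _stage("read census", lambda: _io.read_census(census_path))
    deaths = _stage("read deaths", lambda: _io.read_deaths(deaths_path))

    completeness_rows = []
    summary_rows = []
    measures_rows = []
    tables = {}
    for sex in config.sexes:
        model = _stage(f"ddm inputs [{sex}]",
                       lambda s=sex: DDMModel.from_dataframes(census, deaths, s))
        for method in config.methods:
            res = _stage(
                f"{method} [{sex}]",
                lambda m=method, mo=model: mo.fit(
                    method=m, min_groups=config.min_groups,
                    low=config.min_age, high_end=config.high_end,
                    fit=config.fit,
                    **(
                        {"open_closure_e": config.open_closure_e}
                        if m in ("seg", "ggbseg")
                        and config.open_closure_e is not None
                        else {}
                    ),
                ),
            )
            c = res.completeness
            completeness_rows.append(c.to_frame())
            summary_rows.append(
                (method, sex, c.mean, c.min, c.max,
                 format_estimate(c.mean, c.min, c.max))
            )
            for which in ("min", "mean", "max"):
                lt = _stage(
                    f"life table {method}/{which} [{sex}]",
                    lambda r=res, w=which: r.life_table(w, radix=config.radix),
                )
                tables[(method, sex, which)] = lt
                measures_rows.append(
                    (method, sex, which, res.which_C(which),
                     prob_15_50(lt), lt.e_at(15))
                )
        lt_unadj = _stage(
            f"unadjusted life table [{sex}]",
            lambda mo=model: build_life_table(mo.fit(
                method="seg", min_groups=config.min_groups,
                low=config.min_age, high_end=config.high_end,
            ).unadjusted_rates(), radix=config.radix),
        )
        tables[("unadjusted", sex, "mean")] = lt_unadj
        measures_rows.append(("unadjusted", sex, "mean", 1.0,
                              prob_15_50(lt_unadj), lt_unadj.e_at(15)))

    bundle["completeness"] = pd.concat(completeness_rows, ignore_index=True)
    bundle["completeness_summary"] = pd.DataFrame(
        summary_rows,
        columns=["method", "sex", "mean", "min", "max", "display"],
    )
    bundle["adult_measures"] = pd.DataFrame(
        measures_rows,
        columns=["method", "sex", "which", "C", "q3515", "e15"],
    )

    gap_rows = []
    for method in list(config.methods) + ["unadjusted"]:
        whichs = ("min", "mean", "max") if method != "unadjusted" else ("mean",)
        for which in whichs:
            kf, km = (method, FEMALE, which), (method, MALE, which)
            if kf in tables and km in tables:
                gap_rows.append(
                    (method, which, sexgap_e15(tables[kf], tables[km]))
                )
    bundle["sexgap_e15"] = pd.DataFrame(
        gap_rows, columns=["method", "which", "gap_years"]
    )

    if config.registry_file_a and config.registry_file_b:
        ra = pd.read_csv(config.registry_file_a)
        rb = pd.read_csv(config.registry_file_b)
        bundle["registry_comparison"] = _stage(
            "registry comparison", lambda: compare_registries(ra, rb)
        )

    if config.sibling_file:
        from .survey import SiblingSurveyModel

        sib = pd.read_csv(config.sibling_file)
        model = _stage("sibling model", lambda: SiblingSurveyModel(sib))
        meta["log"].append(
            f"sibling records unusable after imputation: {model.n_unusable}"
        )
        meta["log"].append(f"sibling weight screen: {model.screen}")
        period = config.sibling_period
        if period is None:
            iv = float(sib["interview_date"].iloc[0])
            period = (iv - 10.0, iv)
        res = _stage(
            "sibling fit",
            lambda: model.fit(period, n_boot=config.bootstrap_reps,
                              seed=config.seed),
        )
        bundle["sibling"] = pd.DataFrame(
            [
                (sex, r.period[0], r.period[1], r.q3515,
                 r.conf_int[0], r.conf_int[1])
                for sex, r in res.by_sex.items()
            ],
            columns=["sex", "period_start", "period_end", "q3515",
                     "ci_low", "ci_high"],
        )

    if config.household_file:
        from .survey import HouseholdSurveyModel

        hh = pd.read_csv(config.household_file)
        res = _stage(
            "household fit",
            lambda: HouseholdSurveyModel(hh).fit(
                window_years=config.household_window
            ),
        )
        rows = []
        for sex in res.deaths:
            try:
                rows.append((sex, res.mid_period, res.q3515(sex)))
            except ValueError:
                pass
        bundle["household"] = pd.DataFrame(
            rows, columns=["sex", "mid_period", "q3515"]
        )

    for ref in config.reference_files:
        p = Path(ref)
        bundle.setdefault("references", {})[p.stem] = pd.read_csv(p)

    # serialize
    for key in ("completeness", "completeness_summary", "adult_measures",
                "sexgap_e15", "registry_comparison", "sibling", "household"):
        if key in bundle:
            bundle[key].to_csv(out_dir / f"{key}.csv", index=False)
    for (method, sex, which), lt in tables.items():
        lt.to_csv(out_dir / f"lifetable_{method}_{sex}_{which}.csv")
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    bundle["metadata"] = meta
    return bundle
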