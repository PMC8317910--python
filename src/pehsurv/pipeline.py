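"""Orchestration: run the full analysis over one or many datasets.

A run configuration names datasets (each either a simulation spec or a path to
a ``women.csv``/``children.csv`` pair) plus analysis options; the pipeline
produces, per dataset, the eligibility tally, the descriptive association
table, the screening and adjusted hazard-ratio tables, proportional-hazards
diagnostics, the stratified indirect 5q0 estimates, and forest-plot data --
all as CSV files whose comment headers record the options (and seed) that
produced them, plus a JSON manifest for the run.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, association, brass, cox, recode
from .lifetable import load_standard
from .simulate import SimulationConfig, generate_population, read_child_recode, write_child_recode

__all__ = ["RunConfig", "run_pipeline", "DESCRIPTIVE_FACTORS", "SCREENING_CANDIDATES"]

log = logging.getLogger("pehsurv")

DESCRIPTIVE_FACTORS = [
    "peh", "residence", "religion", "wealth", "sex", "m_age_group", "parity_group",
    "birth_order_group", "water", "toilet", "fuel", "anc_group", "pbi_group",
    "bw_class", "tetanus", "pod",
]
SCREENING_CANDIDATES = [
    "residence", "religion", "wealth", "sex", "m_age_group", "parity_group",
    "birth_order_group", "water", "toilet", "fuel", "anc_group", "pbi_group",
    "bw_class", "tetanus", "pod",
]


@dataclass
class RunConfig:
    """Datasets plus analysis options for one pipeline run."""

    datasets: list = field(default_factory=list)  # dicts: {name, path} or {name, n_women, ...}
    out_dir: str = "results/run"
    seed: int = 0
    tie_method: str = "breslow"
    screening_alpha: float = 0.10
    brass_indices: tuple = brass.DEFAULT_INDICES
    standard: str = "west_pattern_synthetic"
    combine: str = "mean"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown run-config keys: {sorted(bad)}")
        if "brass_indices" in raw:
            raw["brass_indices"] = tuple(raw["brass_indices"])
        return cls(**raw)

    def options(self) -> dict:
        return {
            "tie_method": self.tie_method,
            "screening_alpha": self.screening_alpha,
            "brass_indices": ",".join(map(str, self.brass_indices)),
            "standard": self.standard,
            "combine": self.combine,
            "seed": self.seed,
            "version": __version__,
        }


def write_table(df: pd.DataFrame, path: Path, options: dict) -> None:
    """CSV with ``# key=value`` comment headers recording the provenance."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in options.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Inverse of :func:`write_table`: returns the frame and its options."""
    opts = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            opts[k.strip()] = v
    df = pd.read_csv(path, comment="#")
    return df, opts


def _load_dataset(spec: dict, run: RunConfig):
    """Returns ``(women, children, interview_cmc)`` from a path or sim spec."""
    if "path" in spec:
        women, children = read_child_recode(spec["path"])
        if "interview_cmc" in spec:
            cmc = int(spec["interview_cmc"])
        else:  # latest date consistent with the records
            last = children["birth_cmc"] + children["aad_months"].fillna(0)
            cmc = int(last.max()) if len(children) else 0
        return women, children, cmc
    sim_keys = {k: v for k, v in spec.items() if k != "name"}
    sim_keys.setdefault("seed", run.seed)
    if "log_hr_peh" in sim_keys:
        sim_keys["log_hr_peh"] = tuple(sim_keys["log_hr_peh"])
    cfg = SimulationConfig(**sim_keys)
    women, children = generate_population(cfg)
    return women, children, cfg.interview_cmc


def _analyze_dataset(
    name: str, women, children, interview_cmc: int, out: Path, run: RunConfig
) -> None:
    opts = {"dataset": name, **run.options()}

    kept, tally = recode.apply_exclusions(women, children)
    write_table(
        tally.rename_axis("reason").reset_index(), out / "exclusions.csv", opts
    )
    obs = recode.build_survival_data(women, children, interview_cmc)
    if len(obs) == 0 or obs["event"].sum() == 0:
        raise ValueError("no eligible children with events after exclusions")

    factors = [f for f in DESCRIPTIVE_FACTORS if f in obs.columns]
    write_table(association.u5m_percentage_table(obs, factors), out / "table1.csv", opts)

    candidates = [c for c in SCREENING_CANDIDATES if c in obs.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selected, fits = cox.unadjusted_screen(
            obs, ["peh"] + candidates, alpha=run.screening_alpha, tie_method=run.tie_method
        )
    screen_rows = [
        {
            "variable": var,
            "min_p": fit.summary["p"].min(),
            "selected": var in selected,
        }
        for var, fit in fits.items()
    ]
    write_table(pd.DataFrame(screen_rows), out / "table2_screening.csv", opts)

    adjusted = cox.fit_cox(obs, selected, tie_method=run.tie_method)
    rows = []
    for term in [f"peh={k}" for k in (1, 2, 3)]:
        una = fits["peh"].summary.loc[term] if term in fits["peh"].summary.index else None
        adj = adjusted.summary.loc[term] if term in adjusted.summary.index else None
        rows.append(
            {
                "term": term,
                "unadjusted_hr": None if una is None else una["hr"],
                "unadjusted_ci_low": None if una is None else una["ci_low"],
                "unadjusted_ci_high": None if una is None else una["ci_high"],
                "unadjusted_p": None if una is None else una["p"],
                "adjusted_hr": None if adj is None else adj["hr"],
                "adjusted_ci_low": None if adj is None else adj["ci_low"],
                "adjusted_ci_high": None if adj is None else adj["ci_high"],
                "adjusted_p": None if adj is None else adj["p"],
            }
        )
    write_table(pd.DataFrame(rows), out / "table3_hazard_ratios.csv", opts)
    write_table(
        adjusted.summary.reset_index(), out / "adjusted_model_full.csv", opts
    )

    diag = cox.schoenfeld_test(adjusted)
    diag_df = diag.table.reset_index()
    diag_df.loc[len(diag_df)] = ["GLOBAL", float("nan"), diag.global_chi2, diag.global_df, diag.global_p]
    write_table(diag_df, out / "schoenfeld.csv", opts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        write_table(cox.km_loglog(obs, "peh"), out / "loglog_curves.csv", opts)

    # forest-plot data: extreme-homogamy contrast (both <= primary vs both >= secondary)
    forest = pd.DataFrame(
        [
            {
                "model": m,
                "hr": r["hr"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "p": r["p"],
            }
            for m, r in (
                ("unadjusted", fits["peh"].summary.loc["peh=1"]),
                ("adjusted", adjusted.summary.loc["peh=1"]),
            )
        ]
    )
    write_table(forest, out / "forest.csv", opts)

    eligible = women.loc[
        women["cohabiting"].astype(bool) & women["wife_edu"].notna() & women["husband_edu"].notna()
    ].copy()
    eligible["peh"] = recode.derive_peh_series(eligible["wife_edu"], eligible["husband_edu"]).astype(int)
    standard = load_standard(run.standard)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ests = brass.estimate_u5m_by_stratum(
            eligible, standard, stratifier="peh", indices_used=run.brass_indices, combine=run.combine
        )
    write_table(
        pd.DataFrame(
            [
                {
                    "stratum": e.stratum,
                    "indices_used": ",".join(map(str, e.indices_used)),
                    "alpha": e.alpha,
                    "q5_per_1000": e.q5_per_1000,
                    "standard": e.standard,
                }
                for e in ests
            ]
        ),
        out / "u5m_estimates.csv",
        opts,
    )


def run_pipeline(run: RunConfig) -> dict:
    """Execute every dataset; a stage failure aborts that dataset only.

    Returns ``{"status": {...}, "n_failed": int, "out_dir": str}`` and writes
    ``manifest.json`` recording version, seed, options, and per-dataset status.
    """
    out_root = Path(run.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    for spec in run.datasets:
        name = spec.get("name") or (Path(spec["path"]).name if "path" in spec else "dataset")
        out = out_root / name
        try:
            women, children, interview_cmc = _load_dataset(spec, run)
            out.mkdir(parents=True, exist_ok=True)
            if "path" not in spec:
                write_child_recode(women, children, out / "data")
            _analyze_dataset(name, women, children, interview_cmc, out, run)
            status[name] = "ok"
            log.info("dataset %s: ok", name)
        except Exception as err:  # noqa: BLE001 - isolation contract
            status[name] = f"failed: {err}"
            log.error("dataset %s failed: %s", name, err)
    manifest = {
        "version": __version__,
        "seed": run.seed,
        "options": run.options(),
        "datasets": status,
    }
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"status": status, "n_failed": sum(1 for v in status.values() if v != "ok"), "out_dir": str(out_root)}
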