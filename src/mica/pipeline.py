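"""End-to-end orchestration: prep -> adjusted scans -> stratified clique
discovery -> clique inference with cross-stratum validation -> balance
sensitivity, with seed management and a machine-readable run log.

Every stage's output is a pure function of (inputs, config, master seed):
rerunning with the same configuration reproduces the whole report bundle.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .balance import love_plot, pmm_impute, subclass_balance
from .cohort import SimulationConfig, generate_cohort
from .discovery import (
    DiscoveryConfig,
    candidates_to_frame,
    repeated_holdout_discovery,
    select_cliques,
)
from .inference import build_indicator, cross_stratum_validate, stratified_effects
from .prep import (
    COVARIATE_COLUMNS,
    FeatureTable,
    prepare_metadata,
    prevalence_filter,
    shannon_per_sample,
    to_relative_abundance,
)
from .scan import (
    asv_scan,
    descriptive_frame,
    descriptive_table,
    fit_adjusted_lm,
    fits_to_frame,
    volcano_data,
    volcano_plot,
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    table_path: str | None = None
    meta_path: str | None = None
    simulate: SimulationConfig | None = None
    prevalence_threshold: float = 0.05
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    n_permutations: int = 100_000
    out_dir: str = "mica_run"
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        disc = DiscoveryConfig(**doc.pop("discovery", {}))
        sim = doc.pop("simulate", None)
        sim_cfg = SimulationConfig(**sim) if isinstance(sim, dict) else None
        return cls(discovery=disc, simulate=sim_cfg, **doc)

    def validate(self) -> None:
        if self.simulate is None:
            for p in (self.table_path, self.meta_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the digest of
    its input so the failing run can be reproduced."""

    def __init__(self, stage: str, input_digest: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {input_digest}: {cause}")
        self.stage = stage
        self.input_digest = input_digest


@contextmanager
def _stage(name: str, input_digest: str):
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raise with run context
        raise StageError(name, input_digest, exc) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle to
    ``config.out_dir``.  Returns the in-memory report dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": {}}
    report: dict = {}
    master = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("impute", "discover_secure", "discover_insecure", "infer", "balance"),
            master.spawn(5),
        )
    }
    log["stage_seeds"] = stage_seeds

    # --- load or simulate -------------------------------------------------
    if config.simulate is not None:
        table, meta, truth = generate_cohort(config.simulate)
        mio.write_ground_truth(truth, out / "ground_truth.json")
        report["truth"] = truth
    else:
        table = (
            mio.read_table_biom(config.table_path)
            if str(config.table_path).endswith((".biom", ".json"))
            else mio.read_table_tsv(config.table_path)
        )
        meta = mio.read_metadata_csv(config.meta_path)

    # --- prep -------------------------------------------------------------
    meta = prepare_metadata(meta)
    table = table.subset_samples(meta.index)
    vals = table.values
    if vals.max() > 1.0 + 1e-9 or not np.allclose(vals.sum(axis=1), 1.0, atol=0.05):
        table = to_relative_abundance(table.data)
    shannon = shannon_per_sample(table)
    meta = meta.assign(shannon=shannon)
    filtered = prevalence_filter(table, config.prevalence_threshold)
    meta[COVARIATE_COLUMNS] = pmm_impute(
        meta[COVARIATE_COLUMNS], seed=stage_seeds["impute"]
    )
    log["stages"]["prep"] = {
        "n_samples": len(meta),
        "n_taxa_raw": len(table.taxon_ids),
        "n_taxa_filtered": len(filtered.taxon_ids),
        "meta_digest": _digest(meta),
        "table_digest": _digest(filtered.data),
    }
    report["meta"] = meta
    report["table"] = filtered

    # --- descriptive + preliminary regressions ----------------------------
    desc = descriptive_frame(descriptive_table(meta))
    desc.to_csv(out / "descriptive_table.csv", index=False)
    report["descriptive"] = desc

    y = meta["rci"].to_numpy()
    fi_fit = fit_adjusted_lm(
        y,
        meta["food_insecure"].to_numpy(),
        meta[COVARIATE_COLUMNS],
        exposure_name="food_insecure",
    )
    div_fits = []
    from .scan import stratum_mask

    for stratum in ("secure", "insecure"):
        m = stratum_mask(meta, stratum)
        div_fits.append(
            fit_adjusted_lm(
                y[m],
                meta.loc[m, "shannon"].to_numpy(),
                meta.loc[m, COVARIATE_COLUMNS],
                exposure_name="shannon",
                stratum=stratum,
            )
        )
    prelim = fits_to_frame([fi_fit] + div_fits)
    prelim.to_csv(out / "preliminary_fits.csv", index=False)
    report["preliminary"] = prelim

    # --- per-taxon scans ---------------------------------------------------
    table_digest = log["stages"]["prep"]["table_digest"]
    scans = {}
    for stratum in ("secure", "insecure"):
        with _stage(f"asv_scan_{stratum}", table_digest):
            fits = asv_scan(filtered, meta, stratum=stratum)
        vol = volcano_data(fits)
        vol.to_csv(out / f"asv_scan_{stratum}.csv", index=False)
        if config.make_plots:
            volcano_plot(vol, str(out / f"volcano_{stratum}.png"),
                         title=f"food-{stratum}")
        scans[stratum] = vol
    report["scans"] = scans

    # --- stage 1: discovery per stratum ------------------------------------
    cliques_by_stratum = {}
    for stratum in ("secure", "insecure"):
        m = stratum_mask(meta, stratum)
        disc_cfg = DiscoveryConfig(
            **{
                **config.discovery.__dict__,
                "seed": stage_seeds[f"discover_{stratum}"],
            }
        )
        with _stage(f"discover_{stratum}", table_digest):
            cands = repeated_holdout_discovery(
                filtered.values[m], y[m], disc_cfg, taxon_ids=filtered.taxon_ids
            )
        candidates_to_frame(cands).to_csv(
            out / f"candidates_{stratum}.csv", index=False
        )
        cliques = select_cliques(cands, disc_cfg.min_stability)
        mio.write_cliques(cliques, out / f"cliques_{stratum}.json")
        cliques_by_stratum[stratum] = cliques
        log["stages"][f"discover_{stratum}"] = {
            "n_candidates": len(cands),
            "n_cliques": len(cliques),
            "top_stability": cands[0].stability if cands else 0.0,
        }
    report["cliques"] = cliques_by_stratum

    # --- stage 2: inference + cross-stratum validation ----------------------
    forest_rows = []
    validation_rows = []
    balance_tables = {}
    for stratum, cliques in cliques_by_stratum.items():
        for k, clique in enumerate(cliques):
            with _stage(f"infer_{stratum}_clique{k}", table_digest):
                res = stratified_effects(
                    filtered,
                    meta,
                    clique,
                    n_permutations=config.n_permutations,
                    seed=stage_seeds["infer"] + 97 * k
                    + (0 if stratum == "secure" else 1),
                )
            tab = res.forest_table()
            tab.insert(0, "discovered_in", stratum)
            forest_rows.append(tab)
            val = cross_stratum_validate(
                filtered,
                meta,
                clique,
                discovered_in=stratum,
                n_permutations=config.n_permutations,
                seed=stage_seeds["infer"] + 10_007 + 97 * k,
            )
            validation_rows.append(
                {
                    "discovered_in": stratum,
                    "validated_in": val.stratum,
                    "clique": ",".join(clique.taxa),
                    "beta": val.beta,
                    "ci_low": val.ci95[0],
                    "ci_high": val.ci95[1],
                    "p_robust": val.p_robust,
                }
            )
            # --- balance sensitivity for this clique regression -----------
            indicator = build_indicator(filtered, clique)
            exposure = (indicator.values >= 1).astype(int)
            if 0 < exposure.sum() < len(exposure):
                bal = subclass_balance(exposure, meta[COVARIATE_COLUMNS])
                key = f"{stratum}_clique{k}"
                bal.table.to_csv(out / f"balance_{key}.csv", index=False)
                if config.make_plots:
                    love_plot(bal, str(out / f"love_{key}.png"), title=key)
                balance_tables[key] = bal

    forest = (
        pd.concat(forest_rows, ignore_index=True) if forest_rows else pd.DataFrame()
    )
    forest.to_csv(out / "clique_effects.csv", index=False)
    validation = pd.DataFrame(validation_rows)
    validation.to_csv(out / "cross_stratum_validation.csv", index=False)
    report["clique_effects"] = forest
    report["validation"] = validation
    report["balance"] = balance_tables

    log["stages"]["infer"] = {"n_clique_fits": len(forest)}
    log["report_digest"] = _digest(forest) if len(forest) else ""
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    report["log"] = log
    return report
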