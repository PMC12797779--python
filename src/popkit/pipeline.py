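"""One-config orchestration of the full panel analysis.

Runs, in order: data ingestion or simulation, forensic statistics (allele
frequencies, forensic parameters, HWE and LD screens), kinship LR
simulation, population divergence (F_ST, D_A, I_n), ordination (PCA, MDS,
NJ tree, heatmap ordering) and the ancestry-classification noise protocol.
Each stage gets a seed derived deterministically from the global seed and
the stage name, so disabling one stage does not shift the randomness of
the others; a manifest records stage status, seeds, parameters and input
hashes, and identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import bga, divergence, forensic, kinship, synthetic
from .io import GenotypeTable, read_csv_genotypes, write_csv_genotypes

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

STAGES = ("input", "stats", "kinship", "divergence", "ordination", "bga")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run.

    ``input`` is either ``{"preset": "paper_like", "n_per_pop": ...}`` or
    ``{"csv": path}``.  Per-stage parameter blocks mirror the module
    defaults; a stage block set to ``None``/``false`` is skipped.
    """

    input: dict[str, Any] = field(default_factory=lambda: {"preset": "paper_like"})
    seed: int = 0
    out_dir: str = "popkit_out"
    stats: dict[str, Any] | None = field(default_factory=dict)
    kinship: dict[str, Any] | None = field(default_factory=dict)
    divergence: dict[str, Any] | None = field(default_factory=dict)
    ordination: dict[str, Any] | None = field(default_factory=dict)
    bga: dict[str, Any] | None = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for stage in ("stats", "kinship", "divergence", "ordination", "bga"):
            if raw.get(stage) is False:
                raw[stage] = None
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_input(config: PipelineConfig, out: Path) -> tuple[GenotypeTable, dict]:
    info: dict[str, Any] = dict(config.input)
    if "csv" in config.input:
        table = read_csv_genotypes(config.input["csv"])
        info["sha256"] = _sha256(Path(config.input["csv"]))
    else:
        seed = stage_seed(config.seed, "input")
        table, pf = synthetic.make_reference_panel(
            preset=config.input.get("preset", "paper_like"),
            seed=seed,
            n_per_pop=int(config.input.get("n_per_pop", 20)),
        )
        info["seed"] = seed
        pf.population.to_csv(out / "true_freqs.csv")
    write_csv_genotypes(table, out / "table.csv")
    info["n_samples"], info["n_loci"] = table.n_samples, table.n_loci
    return table, info


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; return (and write) the run manifest.

    A failing stage halts the run with the stage named; outputs of earlier
    stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    caught: list[str] = []

    def _run(stage: str, fn) -> Any:
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                result = fn()
            for w in wlist:
                caught.append(f"{stage}: {w.message}")
            manifest["stages"][stage] = {
                "status": "complete",
                "seed": stage_seed(config.seed, stage),
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return result
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            manifest["warnings"] = caught
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------------ input
    table, info = _run("input", lambda: _load_input(config, out))
    manifest["input"] = info

    freqs = forensic.allele_frequencies(table)
    sup_freqs = freqs.mean_by_group(table.population_to_superpopulation())

    # ------------------------------------------------------------------ stats
    if config.stats is not None:
        def _stats():
            d = out / "stats"
            d.mkdir(exist_ok=True)
            freqs.to_csv(d / "frequencies.csv")
            fp = forensic.forensic_param_table(table)
            fp.to_csv(d / "forensic_params.csv", index=False, float_format="%.6f")
            pd.DataFrame(
                [(p, c[0], c[1]) for p, c in fp.attrs["cumulative"].items()],
                columns=["population", "CPD", "CPE"],
            ).to_csv(d / "cumulative_power.csv", index=False, float_format="%.6f")
            forensic.hwe_test_table(table).to_csv(
                d / "hwe.csv", index=False, float_format="%.6f"
            )
            forensic.ld_test_table(
                table,
                n_perm=int(config.stats.get("ld_permutations", 199)),
                seed=stage_seed(config.seed, "stats"),
            ).to_csv(d / "ld.csv", index=False, float_format="%.6f")
        _run("stats", _stats)
    else:
        manifest["stages"]["stats"] = {"status": "skipped"}

    # ---------------------------------------------------------------- kinship
    if config.kinship is not None:
        def _kinship():
            d = out / "kinship"
            d.mkdir(exist_ok=True)
            cfg = config.kinship
            pops = cfg.get("populations") or [freqs.populations[-1]]
            models = [kinship.get_model(m)
                      for m in cfg.get("models", ("full_sibling", "half_sibling"))]
            thresholds = cfg.get("thresholds", (1, 10, 100, 1000, 10000))
            n_pairs = int(cfg.get("n_pairs", 1000))
            seed = stage_seed(config.seed, "kinship")
            lr_rows, acc_rows = [], []
            for i, pop in enumerate(pops):
                f = freqs.for_population(pop)
                for k, model in enumerate(models):
                    sim = kinship.simulate_pairs(
                        f, model, n_pairs, seed=seed + 7919 * i + k
                    )
                    null = kinship.simulate_pairs(
                        f, kinship.UNRELATED, n_pairs,
                        seed=seed + 7919 * i + k + 104729, lr_model=model,
                    )
                    for v in sim.log10_lr:
                        lr_rows.append((pop, model.name, "related", float(v)))
                    for v in null.log10_lr:
                        lr_rows.append((pop, model.name, "unrelated", float(v)))
                    sens = kinship.threshold_accuracy(sim.log10_lr, thresholds)
                    fpr = kinship.threshold_accuracy(null.log10_lr, thresholds)
                    for t in thresholds:
                        acc_rows.append(
                            (pop, model.name, t, sens[float(t)], fpr[float(t)])
                        )
            pd.DataFrame(
                lr_rows, columns=["population", "model", "hypothesis", "log10_lr"]
            ).to_csv(d / "log10lr.csv", index=False, float_format="%.6f")
            pd.DataFrame(
                acc_rows,
                columns=["population", "model", "threshold", "sensitivity",
                         "false_positive_rate"],
            ).to_csv(d / "accuracy.csv", index=False, float_format="%.6f")
        _run("kinship", _kinship)
    else:
        manifest["stages"]["kinship"] = {"status": "skipped"}

    # ------------------------------------------------------------- divergence
    if config.divergence is not None:
        def _divergence():
            d = out / "divergence"
            d.mkdir(exist_ok=True)
            divergence.fst_matrix(freqs).to_csv(d / "fst.csv")
            divergence.da_matrix(freqs).to_csv(d / "da.csv")
            sups = list(dict.fromkeys(table.superpopulation))
            rows = []
            for sup in sups:
                cum, per = divergence.cumulative_in(sup_freqs, sup)
                rows += [(f"{sup}_vs_rest", lid, v) for lid, v in per.items()]
                rows.append((f"{sup}_vs_rest", "CUMULATIVE", cum))
            for i, a in enumerate(sups):
                for b in sups[i + 1:]:
                    cum, _ = divergence.cumulative_in(sup_freqs, (a, b))
                    rows.append((f"{a}_vs_{b}", "CUMULATIVE", cum))
            pd.DataFrame(rows, columns=["grouping", "locus_id", "I_n"]).to_csv(
                d / "in_values.csv", index=False, float_format="%.6f"
            )
        _run("divergence", _divergence)
    else:
        manifest["stages"]["divergence"] = {"status": "skipped"}

    # ------------------------------------------------------------- ordination
    if config.ordination is not None:
        def _ordination():
            d = out / "ordination"
            d.mkdir(exist_ok=True)
            mat = freqs.matrix()
            res = divergence.pca(mat, standardize=True)
            res.coordinates.to_csv(d / "pca_coords.csv", float_format="%.6f")
            res.cos2.to_csv(d / "pca_cos2.csv", float_format="%.6f")
            res.contributions.to_csv(d / "pca_contrib.csv", float_format="%.6f")
            fst = divergence.fst_matrix(freqs)
            mds = divergence.classical_mds(fst, k=2)
            mds.coordinates.to_csv(d / "mds_coords.csv", float_format="%.6f")
            da = divergence.da_matrix(freqs)
            (d / "nj_tree.nwk").write_text(divergence.nj_tree(da) + "\n")
            order = divergence.hclust_order(mat)
            (d / "heatmap_order.json").write_text(json.dumps({
                "rows": order["row_order"], "cols": order["col_order"]
            }, indent=2))
        _run("ordination", _ordination)
    else:
        manifest["stages"]["ordination"] = {"status": "skipped"}

    # -------------------------------------------------------------------- bga
    if config.bga is not None:
        def _bga():
            d = out / "bga"
            d.mkdir(exist_ok=True)
            cfg = config.bga
            seed = stage_seed(config.seed, "bga")
            is_target = np.isin(
                table.population, cfg.get("external_populations", [])
            )
            ref = table.subset_samples(np.flatnonzero(~is_target))
            ext = (table.subset_samples(np.flatnonzero(is_target))
                   if is_target.any() else None)
            train, test = bga.stratified_split(
                ref, test_size=float(cfg.get("test_size", 0.2)), seed=seed
            )
            enc = bga.DosageEncoder().fit(train)
            Xtr, Xte = enc.transform(train), enc.transform(test)
            svm_cfg = bga.SvmConfig(
                budget=int(cfg.get("budget", 40)), seed=seed
            )
            model, chosen = bga.tune_and_train(
                Xtr, train.superpopulation, svm_cfg
            )
            (d / "chosen_hyperparams.json").write_text(
                json.dumps(chosen, indent=2)
            )
            result = bga.noise_experiment(
                Xtr, train.superpopulation, Xte, test.superpopulation,
                enc.transform(ext) if ext else None,
                ext.superpopulation if ext else None,
                fractions=cfg.get("fractions", bga.DEFAULT_NOISE_FRACTIONS),
                repetitions=int(cfg.get("repetitions", 10)),
                seed=seed,
                config=svm_cfg,
            )
            result.records.to_csv(
                d / "f1_by_fraction_reps.csv", index=False, float_format="%.6f"
            )
            result.summary().to_csv(
                d / "f1_by_fraction.csv", index=False, float_format="%.6f"
            )
        _run("bga", _bga)
    else:
        manifest["stages"]["bga"] = {"status": "skipped"}

    manifest["warnings"] = caught
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
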