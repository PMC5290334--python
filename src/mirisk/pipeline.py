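"""End-to-end orchestration: simulate/load -> normalize -> train -> validate
-> networks -> sequence similarity, with seeded reproducibility.

A single master seed deterministically derives one seed per stage (CRC32
of ``"<master>:<stage>"``), so any stage can be re-run in isolation and
reproduce its in-pipeline behaviour.  Every intermediate artifact is
written to the output directory and all key numbers end up in one
machine-readable JSON report; a second run with the same configuration
produces a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirisk import alignment, calf, networks, preprocess, quantify, validation
from mirisk.synthetic import CohortConfig, generate_cohort

log = logging.getLogger("mirisk")

REPORT_SCHEMA_VERSION = 1


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{master}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters and file paths for one pipeline run."""

    outdir: str = "mirisk-out"
    # inputs: either paths to counts/metadata, or simulate=True
    counts_path: str | None = None
    metadata_path: str | None = None
    mature_fasta: str | None = None  # enables the sequence-similarity stage
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    # preprocessing
    min_total: int = 10000
    max_fraction: float = 0.5
    top_k: int = 30
    reference: str = "unaffected"
    # classifier
    pos_group: str = "progressed"
    neg_group: str = "nonprogressed"
    max_markers: int = 6
    # validation
    n_perm: int = 1000
    n_stability: int = 1000
    subset_fraction: float = 0.8
    stability_min_count_fraction: float = 0.225
    n_subset_trials: int = 1000
    subset_size: int = 25
    # networks
    network_top_k: int = 40
    network_subset_size: int = 25
    network_trials: int = 1000
    p_tail: float = 0.001
    edge_min_fraction: float = 0.5
    # sequence similarity
    seqsim_trials: int = 1000
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**payload)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate:
        overrides = dict(config.cohort)
        overrides.setdefault("seed", stage_seed(config.seed, "simulate"))
        cohort = generate_cohort(CohortConfig(**overrides))
        cohort.write(
            outdir / "counts.tsv", outdir / "metadata.csv", outdir / "truth.json"
        )
        return cohort.counts, cohort.metadata
    for name, path in (("counts", config.counts_path), ("metadata", config.metadata_path)):
        if path is None or not Path(path).exists():
            raise StageError("load", f"missing {name} file: {path!r}")
    counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
    metadata = pd.read_csv(config.metadata_path)
    return counts, metadata


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(config),
        "stages": {},
    }

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is None:
                    log.info("stage %s finished in %.2fs", stage, time.perf_counter() - self.t0)

        return _T()

    # --- load / simulate -------------------------------------------------
    with timed("load"):
        counts, metadata = _load_inputs(config, outdir)
    report["stages"]["input"] = {
        "n_mirnas": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "groups": metadata["group"].value_counts().to_dict(),
    }

    # --- normalize --------------------------------------------------------
    with timed("normalize"):
        robust = preprocess.filter_robust(counts, min_total=config.min_total)
        if not robust:
            raise StageError("normalize", "no miRNA passed the robustness filter")
        counts_r = counts.loc[robust]
        kept, dropped = preprocess.drop_superabundant(counts_r, config.max_fraction)
        counts_k = counts_r.loc[kept]
        q = preprocess.quotient_normalize(counts_k, top_k=min(config.top_k, len(kept)))
        z = preprocess.zscore_reference(q, metadata, reference=config.reference)
        z.to_csv(outdir / "zscores.tsv", sep="\t", index_label="mirna")
    report["stages"]["normalize"] = {
        "n_robust": len(robust),
        "superabundant_dropped": [m for m, _ in dropped],
        "n_final": len(kept),
    }

    # --- train ------------------------------------------------------------
    with timed("train"):
        two = metadata[metadata["group"].isin([config.neg_group, config.pos_group])]
        samples = [s for s in two["sample_id"] if s in z.columns]
        labels = (
            two.set_index("sample_id").loc[samples, "group"] == config.pos_group
        ).to_numpy()
        z2 = z[samples]
        model = calf.greedy_calf(z2, labels, max_markers=config.max_markers)
        model.to_json(outdir / "model.json")
    report["stages"]["train"] = {
        "terms": [{"mirna": m, "weight": w} for m, w in model.terms],
        "metric_trace": model.metric_trace,
        "training_auc": model.final_auc,
    }

    # --- validate ---------------------------------------------------------
    with timed("validate"):
        perm = validation.permutation_test(
            z2, labels, n_perm=config.n_perm, max_markers=config.max_markers,
            seed=stage_seed(config.seed, "permutation"),
        )
        stab = validation.stability_selection(
            z2, labels, subset_fraction=config.subset_fraction,
            n_trials=config.n_stability, max_markers=config.max_markers,
            seed=stage_seed(config.seed, "stability"),
        )
        min_count = int(round(config.stability_min_count_fraction * config.n_stability))
        try:
            integrated = validation.integrate_classifier(stab, model, min_count=min_count)
        except ValueError as exc:
            raise StageError("validate", str(exc)) from exc
        integrated.final_auc = calf.auc(
            calf.score_samples(integrated, z2).to_numpy(), labels
        )
        integrated.to_json(outdir / "integrated_model.json")
        n_sub = min(config.subset_size, int(labels.sum()), int((~labels).sum()))
        mean_auc, sd_auc, _ = validation.subset_auc_distribution(
            integrated, z2, labels, n_per_group=n_sub,
            n_trials=config.n_subset_trials,
            seed=stage_seed(config.seed, "subsets"),
        )
        np.savetxt(outdir / "pseudo_aucs.tsv", perm.pseudo_aucs, fmt="%.6f")
        stab.counts.to_csv(outdir / "stability_counts.tsv", sep="\t", header=["count"])
        confound = {}
        if "medicated" in metadata.columns:
            flag = (
                two.set_index("sample_id").loc[samples, "medicated"].astype(bool).to_numpy()
            )
            for mode in ("maximize", "minimize"):
                aucs = validation.confound_extremal_subsets(
                    integrated, z2, labels, flag, n_per_group=n_sub,
                    n_trials=config.n_subset_trials, mode=mode,
                    seed=stage_seed(config.seed, f"confound-{mode}"),
                )
                confound[mode] = {
                    "mean": float(aucs.mean()),
                    "min": float(aucs.min()),
                    "max": float(aucs.max()),
                }
    report["stages"]["validate"] = {
        "true_auc": perm.true_auc,
        "p_montecarlo": perm.p_montecarlo,
        "p_beta": perm.p_beta,
        "stability_min_count": min_count,
        "stable_markers": stab.stable_set(min_count),
        "integrated_terms": [{"mirna": m, "weight": w} for m, w in integrated.terms],
        "integrated_auc": integrated.final_auc,
        "subset_auc_mean": mean_auc,
        "subset_auc_sd": sd_auc,
        "confound_auc": confound,
    }

    # --- networks ----------------------------------------------------------
    with timed("networks"):
        k = min(config.network_top_k, len(kept))
        nodes = networks.top_abundant_nodes(counts_k, k=k)
        r_thr = networks.critical_correlation(config.p_tail, config.network_subset_size)
        edge_min = int(round(config.edge_min_fraction * config.network_trials))
        nets = []
        for group, cnt in metadata["group"].value_counts().items():
            if cnt < config.network_subset_size:
                log.warning("group %s too small for networks (%d samples); skipped", group, cnt)
                continue
            table = networks.subsample_exceedance_counts(
                z, metadata, group, nodes,
                subset_size=config.network_subset_size,
                n_trials=config.network_trials, r_threshold=r_thr,
                seed=stage_seed(config.seed, f"network-{group}"),
            )
            net = networks.build_network(
                table, edge_min=edge_min, group=group,
                n_trials=config.network_trials, nodes=nodes,
                params={"r_threshold": r_thr, "subset_size": config.network_subset_size},
            )
            table.to_csv(outdir / f"paircounts_{group}.tsv", sep="\t", index=False)
            networks.export_pajek(net, outdir / f"network_{group}.net")
            nets.append(net)
        comparison = networks.compare_networks(nets) if nets else {}
        with open(outdir / "network_comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=1, sort_keys=True)
    report["stages"]["networks"] = {
        "r_threshold": r_thr,
        "edge_min": edge_min,
        "edge_counts": comparison.get("edge_counts", {}),
    }

    # --- sequence similarity ------------------------------------------------
    if config.mature_fasta:
        with timed("seqsim"):
            mirnas = quantify.load_mature_fasta(config.mature_fasta)
            by_id = {m.id: m for m in mirnas}
            selected = [by_id[m] for m, _ in model.terms if m in by_id]
            pool = [m for m in mirnas if m.id not in {s.id for s in selected}]
            if len(selected) >= 2 and len(pool) >= len(selected):
                obs, null, p = alignment.similarity_null_test(
                    selected, pool, n_trials=config.seqsim_trials,
                    seed=stage_seed(config.seed, "seqsim"),
                )
                report["stages"]["seqsim"] = {
                    "observed_mean": obs,
                    "null_mean": float(null.mean()),
                    "p_montecarlo": p,
                }
            else:
                report["stages"]["seqsim"] = {"skipped": "not enough sequences"}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
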