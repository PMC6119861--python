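"""Ground-truth-labelled synthetic cohorts emulating CAGE promoter time courses.

Two noise regimes are provided, matching their two uses:

* the calibration scheme — one noise-free replicate plus two replicates
  offset by +noise and −noise (the scheme used to measure complexity
  offsets);
* iid Gaussian replicate noise — used for realistic multi-dataset cohorts
  with planted model classes, planted known-IEG labels enriched among
  peak-class genes, and a planted roster of genes peaking in a strict
  common order across datasets (rank-spaced base peak times plus per-dataset
  jitter).

Cohorts are emitted on the TPM scale by inverse-normalizing each model
trajectory with randomized per-TSS anchors, so the downstream pipeline
(TPM filtering, normalization, fitting, meta-analysis) sees data of the
shape it expects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (DatasetBundle, TimeCourse, write_expression_table,
                         write_gene_labels)
from .kinetic_models import ModelSpec, NormalizedSeries, build_model_set, eval_model
from .ordering_network import PeakTimeMatrix

#: per-dataset sampling grids (minutes): dense early sampling, irregular,
#: varying spans, emulating stimulus-response time-course designs
DEFAULT_GRIDS = (
    (0, 15, 30, 45, 60, 80, 100, 120, 160, 200, 240, 300),
    (0, 15, 30, 45, 60, 90, 120, 150, 180, 240, 300, 360),
    (0, 10, 20, 40, 60, 80, 120, 160, 200, 260, 320, 400),
    (0, 15, 30, 60, 90, 120, 150, 200, 250, 300),
    (0, 20, 40, 60, 80, 100, 140, 180, 240, 300, 360),
    (0, 15, 30, 45, 60, 100, 140, 180, 220, 280, 340),
    (0, 10, 25, 40, 60, 85, 110, 150, 190, 240, 300),
    (0, 15, 35, 55, 75, 100, 130, 170, 210, 260, 320, 380),
)

CLASS_NAMES = ("peak", "linear", "decay", "dip", "flat")


def generate_calibration_series(spec: ModelSpec, params, times,
                                noise: float) -> NormalizedSeries:
    """Three-replicate series: exact trajectory, +noise, −noise.

    The same noise value is applied at every time point, so the per-time
    replicate spread is exactly 2·noise and the per-time median equals the
    noise-free trajectory.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    t = np.asarray(times, dtype=float)
    traj = eval_model(spec, params, t)
    values = np.stack([traj, traj + noise, traj - noise])
    return NormalizedSeries(times=t, values=values, anchor_min=0.0,
                            anchor_max=10.0, tss_id="calibration",
                            dataset_id="synthetic")


def planted_peak_time_matrix(n_genes: int = 20, n_datasets: int = 8,
                             t_first: float = 30.0, spacing: float = 20.0,
                             jitter_sd: float = 5.0, seed: int = 0):
    """Peak-time matrix with a strict common gene ordering across datasets.

    Gene of rank r has base peak time ``t_first + r*spacing``; each dataset
    observes it with iid Gaussian jitter. Returns (matrix, genes in rank
    order). Spacing default 20 min against 5 min jitter keeps adjacent ranks
    separated by ~2.8 sd of their per-dataset difference.
    """
    rng = np.random.default_rng(seed)
    genes = [f"ORD{r:03d}" for r in range(n_genes)]
    base = t_first + spacing * np.arange(n_genes)
    tp = base[:, None] + rng.normal(0.0, jitter_sd, size=(n_genes, n_datasets))
    tp = np.clip(tp, 1.0, None)
    frame = pd.DataFrame(tp, index=genes,
                         columns=[f"DS{j + 1}" for j in range(n_datasets)])
    return PeakTimeMatrix(frame=frame), genes


@dataclass
class SyntheticConfig:
    """Cohort generator settings; defaults emulate an 8-dataset design."""

    n_datasets: int = 8
    grids: tuple = DEFAULT_GRIDS
    n_coding: int = 270
    n_noncoding: int = 30
    #: class mixture over non-roster genes (fractions sum to 1; "flat" means
    #: no temporal signal, hence unclassifiable by design)
    class_mixture: dict = field(default_factory=lambda: {
        "peak": 0.35, "linear": 0.20, "decay": 0.15, "dip": 0.10, "flat": 0.20})
    #: distribution of TSS count per gene
    tss_count_probs: tuple = ((1, 0.6), (2, 0.3), (3, 0.1))
    #: baseline IEG label rate for non-peak genes; peak-class genes are
    #: labelled at ieg_enrichment-fold higher odds
    ieg_base_rate: float = 0.03
    ieg_enrichment: float = 5.0
    #: planted strict-ordering roster (always peak-class, always labelled IEG)
    n_ordered: int = 10
    order_t_first: float = 30.0
    order_spacing: float = 25.0
    order_jitter_sd: float = 5.0
    #: iid Gaussian replicate noise, normalized units
    noise_sd: float = 0.3
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class mixture fractions must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")
        if self.n_datasets > len(self.grids):
            raise ValueError("not enough sampling grids for n_datasets")
        for grid in self.grids:
            g = np.asarray(grid, dtype=float)
            if g[0] != 0 or np.any(np.diff(g) <= 0):
                raise ValueError("grids must increase strictly from 0")

    def to_json(self, path) -> None:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        payload["grids"] = [list(g) for g in self.grids]
        payload["tss_count_probs"] = [list(p) for p in self.tss_count_probs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """Generator bookkeeping: per-gene and per-TSS truth tables."""

    genes: pd.DataFrame            # gene_id, biotype, class, ieg, order_rank
    tss: pd.DataFrame              # dataset_id, tss_id, gene_id, class, true_tp
    peak_times: PeakTimeMatrix     # true earliest t_p per peak gene x dataset
    ieg_labels: set

    def roster_genes(self):
        ranked = self.genes.dropna(subset=["order_rank"]).sort_values("order_rank")
        return list(ranked["gene_id"])

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        self.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.tss.to_csv(out / "truth_tss.tsv", sep="\t", index=False)
        self.peak_times.to_tsv(out / "truth_peak_times.tsv")
        write_gene_labels(self.ieg_labels, out / "ieg_labels.txt")


def _draw_peak_params(rng, t_max, tp=None):
    """Realistic immediate-early-like peak parameters (normalized scale)."""
    p1 = rng.uniform(0.2, 2.0)
    p2 = rng.uniform(4.0, 9.0)
    if tp is None:
        td = rng.uniform(0.0, 0.25 * t_max)
        ts = rng.uniform(15.0, 0.45 * t_max)
    else:
        tp = min(max(tp, 6.0), 1.7 * t_max)
        td = rng.uniform(0.1, 0.4) * tp
        ts = tp - td
    r_rise = rng.uniform(0.02, 0.2)
    r_fall = rng.uniform(0.005, 0.05)
    return np.array([p1, p2, td, ts, r_rise, r_fall])


def _draw_class_params(rng, cls, t_max, tp=None):
    if cls == "peak":
        return _draw_peak_params(rng, t_max, tp=tp)
    if cls == "linear":
        slope = rng.uniform(-8.0, 8.0) / t_max
        return np.array([rng.uniform(1.0, 9.0), slope])
    if cls == "decay":
        return np.array([rng.uniform(0.0, 2.0), rng.uniform(4.0, 9.0),
                         rng.uniform(0.01, 0.1)])
    if cls == "dip":
        return np.array([rng.uniform(6.0, 9.0), rng.uniform(4.0, 8.0),
                         rng.uniform(0.005, 0.02), rng.uniform(0.05, 0.3)])
    if cls == "flat":
        return np.array([rng.uniform(2.0, 8.0), 0.0])
    raise ValueError(f"unknown class '{cls}'")


def generate_cohort(config: SyntheticConfig):
    """Generate one multi-dataset cohort.

    Returns (bundles, truth): ``bundles`` maps dataset_id to a
    :class:`DatasetBundle` on the TPM scale; ``truth`` records the
    generating class, parameters and true peak times of every TSS, the
    planted IEG labels and the ordering roster.
    """
    rng = np.random.default_rng(config.seed)
    datasets = [f"DS{j + 1}" for j in range(config.n_datasets)]
    grids = {ds: np.asarray(config.grids[j], dtype=float)
             for j, ds in enumerate(datasets)}

    # --- gene roster -----------------------------------------------------
    classes = list(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in classes])
    gene_rows = []
    n_total = config.n_coding + config.n_noncoding
    if config.n_ordered > config.n_coding:
        raise ValueError("ordering roster larger than coding gene count")
    for i in range(n_total):
        biotype = "coding" if i < config.n_coding else "noncoding"
        rank = i if i < config.n_ordered else None
        if rank is not None:
            cls = "peak"
        else:
            cls = classes[rng.choice(len(classes), p=probs)]
        gene_rows.append({"gene_id": f"G{i:04d}", "biotype": biotype,
                          "class": cls, "order_rank": rank})
    genes = pd.DataFrame(gene_rows)

    # planted IEG labels: roster genes always labelled; elsewhere the odds of
    # a label are ieg_enrichment-fold higher for peak-class genes
    p_base = config.ieg_base_rate
    odds = p_base / (1 - p_base) * config.ieg_enrichment
    p_peak = odds / (1 + odds)
    ieg = []
    for row in gene_rows:
        if row["order_rank"] is not None:
            flagged = True
        else:
            p = p_peak if row["class"] == "peak" else p_base
            flagged = rng.random() < p
        ieg.append(flagged)
    genes["ieg"] = ieg
    ieg_labels = set(genes.loc[genes["ieg"], "gene_id"])

    # planted peak-time schedule for roster genes
    base_tp = {int(r): config.order_t_first + config.order_spacing * int(r)
               for r in genes["order_rank"].dropna()}

    # --- per-dataset emission -------------------------------------------
    n_rep = config.n_replicates
    bundles = {}
    tss_rows = []
    true_tp = pd.DataFrame(np.nan, index=genes["gene_id"], columns=datasets)
    tss_counts = {g: rng.choice([k for k, _ in config.tss_count_probs],
                                p=[p for _, p in config.tss_count_probs])
                  for g in genes["gene_id"]}
    for ds in datasets:
        times = grids[ds]
        t_max = float(times[-1])
        tcs = []
        for gi, row in genes.iterrows():
            gene_id, cls, biotype = row["gene_id"], row["class"], row["biotype"]
            planted_tp = None
            if pd.notna(row["order_rank"]):
                planted_tp = float(base_tp[int(row["order_rank"])]
                                   + rng.normal(0.0, config.order_jitter_sd))
                planted_tp = max(planted_tp, 6.0)
            gene_min_tp = np.inf
            for k in range(tss_counts[gene_id]):
                # the first TSS carries the gene's planted timing; secondary
                # promoters of roster genes peak later, so the earliest-TSS
                # rule downstream recovers the planted gene-level t_p
                if planted_tp is None:
                    tp_k = None
                elif k == 0:
                    tp_k = planted_tp
                else:
                    tp_k = planted_tp + rng.uniform(20.0, 120.0)
                params = _draw_class_params(rng, cls, t_max, tp=tp_k)
                if cls == "peak":
                    tss_tp = float(params[2] + params[3])
                    gene_min_tp = min(gene_min_tp, tss_tp)
                else:
                    tss_tp = np.nan
                model_id_name = "linear" if cls == "flat" else cls
                spec = _spec_for(model_id_name, t_max)
                traj = eval_model(spec, _clip_params(params, spec), times)
                noisy = traj[None, :] + rng.normal(
                    0.0, config.noise_sd, size=(n_rep, times.size))
                # inverse-normalize to TPM with randomized anchors; spans keep
                # maxima above the biotype's filtering threshold
                if biotype == "coding":
                    m, span = rng.uniform(0.0, 8.0), rng.uniform(20.0, 200.0)
                else:
                    m, span = rng.uniform(0.0, 2.0), rng.uniform(5.0, 40.0)
                tpm = np.clip(m + noisy * (span / 10.0), 0.0, None)
                tss_id = f"{gene_id}.p{k + 1}"
                tcs.append(TimeCourse(tss_id=tss_id, gene_id=gene_id,
                                      biotype=biotype, dataset_id=ds,
                                      times=times, expression=tpm))
                tss_rows.append({"dataset_id": ds, "tss_id": tss_id,
                                 "gene_id": gene_id, "class": cls,
                                 "true_tp": tss_tp,
                                 "params": ";".join(f"{v:.6g}" for v in params)})
            if np.isfinite(gene_min_tp):
                true_tp.loc[gene_id, ds] = gene_min_tp
        bundles[ds] = DatasetBundle(dataset_id=ds, timecourses=tcs,
                                    ieg_labels=set(ieg_labels))
    truth = GroundTruth(genes=genes, tss=pd.DataFrame(tss_rows),
                        peak_times=PeakTimeMatrix(
                            frame=true_tp.dropna(how="all")),
                        ieg_labels=ieg_labels)
    return bundles, truth


def _spec_for(name: str, t_max: float) -> ModelSpec:
    models = build_model_set(t_max)
    if name == "peak":
        return models["peak_fast"]
    return models[name]


def _clip_params(params, spec: ModelSpec):
    """Clip generator draws into the model's prior box (e.g. planted peak
    times that overrun the box after jitter)."""
    return np.clip(params, spec.lower, spec.upper)


def write_cohort(bundles: dict, truth: GroundTruth, outdir,
                 config: SyntheticConfig = None) -> list:
    """Emit a cohort as TSV tables; returns the list of files written."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for ds, bundle in bundles.items():
        path = out / f"{ds}.expression.tsv"
        write_expression_table(bundle, path)
        written.append(path)
    truth.write(out)
    written += [out / "truth_genes.tsv", out / "truth_tss.tsv",
                out / "truth_peak_times.tsv", out / "ieg_labels.txt"]
    if config is not None:
        cfg_path = out / "generator_config.json"
        config.to_json(cfg_path)
        written.append(cfg_path)
    return written
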