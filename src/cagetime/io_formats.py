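"""Input/output: expression tables, gene label lists, configs and results.

The expression-table dialect is a plain TSV with columns::

    tss_id  gene_id  biotype  t<minutes>_r<replicate>  ...

one row per TSS, expression in TPM. Time/replicate columns are parsed from
the header; times must be shared by every row of a dataset (they are a
property of the experiment, not the TSS). Gene label lists (e.g. known
immediate early genes) are one gene id per line, ``#`` comments allowed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cagetime")

_TIME_COL = re.compile(r"^t(\d+(?:\.\d+)?)_r(\d+)$")

BIOTYPES = ("coding", "noncoding")


@dataclass
class TimeCourse:
    """One TSS's replicated TPM trajectory within one dataset."""

    tss_id: str
    gene_id: str
    biotype: str
    dataset_id: str
    times: np.ndarray              # minutes, strictly increasing
    expression: np.ndarray         # (replicates, times), TPM

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype '{self.biotype}'")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times must be strictly increasing ({self.tss_id})")
        if self.expression.ndim != 2 or self.expression.shape[1] != self.times.size:
            raise ValueError(f"expression shape mismatch for '{self.tss_id}'")
        if self.expression.shape[0] < 2:
            raise ValueError(f"need >=2 replicates for '{self.tss_id}'")
        if np.any(~np.isfinite(self.expression)):
            raise ValueError(f"missing/non-finite TPM in '{self.tss_id}'")
        if np.any(self.expression < 0):
            raise ValueError(f"negative TPM in '{self.tss_id}'")

    @property
    def max_tpm(self) -> float:
        return float(self.expression.max())


@dataclass
class DatasetBundle:
    """All TimeCourses of one dataset plus known-IEG labels."""

    dataset_id: str
    timecourses: list
    ieg_labels: set = field(default_factory=set)

    def __post_init__(self):
        seen = set()
        for tc in self.timecourses:
            if tc.tss_id in seen:
                raise ValueError(
                    f"duplicate tss_id '{tc.tss_id}' in dataset '{self.dataset_id}'")
            seen.add(tc.tss_id)
        if self.timecourses:
            t0 = self.timecourses[0].times
            for tc in self.timecourses[1:]:
                if tc.times.size != t0.size or np.any(tc.times != t0):
                    raise ValueError(
                        f"'{tc.tss_id}' does not share the dataset sampling times")

    def __len__(self):
        return len(self.timecourses)

    @property
    def times(self) -> np.ndarray:
        if not self.timecourses:
            return np.empty(0)
        return self.timecourses[0].times


def _parse_header(columns):
    """Map header columns to (time, replicate); returns sorted structure."""
    entries = []
    for i, col in enumerate(columns):
        m = _TIME_COL.match(col)
        if m is None:
            raise ValueError(f"malformed time/replicate column '{col}'"
                             " (expected t<minutes>_r<k>)")
        entries.append((float(m.group(1)), int(m.group(2)), i))
    times = sorted({t for t, _, _ in entries})
    reps = sorted({r for _, r, _ in entries})
    index = {}
    for t, r, i in entries:
        if (t, r) in index:
            raise ValueError(f"duplicate column for t={t:g} r={r}")
        index[(t, r)] = i
    for t in times:
        for r in reps:
            if (t, r) not in index:
                raise ValueError(f"missing column t{t:g}_r{r}")
    return np.asarray(times), reps, index


def read_expression_table(path, dataset_id: str) -> DatasetBundle:
    """Read a TSV expression table into a :class:`DatasetBundle`."""
    df = pd.read_csv(path, sep="\t", dtype={"tss_id": str, "gene_id": str},
                     float_precision="round_trip")
    meta_cols = [c for c in ("tss_id", "gene_id", "biotype") if c in df.columns]
    if set(meta_cols) != {"tss_id", "gene_id", "biotype"}:
        raise ValueError(f"{path}: missing required columns "
                         "tss_id/gene_id/biotype")
    value_cols = [c for c in df.columns if c not in meta_cols]
    times, reps, index = _parse_header(value_cols)
    tcs = []
    for row_i, row in df.iterrows():
        expr = np.empty((len(reps), times.size))
        for ri, r in enumerate(reps):
            for ti, t in enumerate(times):
                val = row[value_cols[index[(t, r)]]]
                if pd.isna(val):
                    raise ValueError(
                        f"{path}: missing TPM at row {row_i} ('{row['tss_id']}'),"
                        f" column t{t:g}_r{r}")
                if val < 0:
                    raise ValueError(
                        f"{path}: negative TPM at row {row_i} ('{row['tss_id']}'),"
                        f" column t{t:g}_r{r}")
                expr[ri, ti] = val
        tcs.append(TimeCourse(tss_id=str(row["tss_id"]), gene_id=str(row["gene_id"]),
                              biotype=str(row["biotype"]), dataset_id=dataset_id,
                              times=times, expression=expr))
    return DatasetBundle(dataset_id=dataset_id, timecourses=tcs)


def write_expression_table(bundle: DatasetBundle, path) -> None:
    """Write a bundle back to the TSV dialect at full float precision."""
    if not bundle.timecourses:
        raise ValueError("cannot write an empty bundle")
    times = bundle.times
    n_rep = bundle.timecourses[0].expression.shape[0]
    cols = [f"t{t:g}_r{r}" for t in times for r in range(1, n_rep + 1)]
    with open(path, "w") as fh:
        fh.write("tss_id\tgene_id\tbiotype\t" + "\t".join(cols) + "\n")
        for tc in bundle.timecourses:
            vals = [repr(float(tc.expression[r, ti]))
                    for ti in range(times.size) for r in range(n_rep)]
            fh.write(f"{tc.tss_id}\t{tc.gene_id}\t{tc.biotype}\t"
                     + "\t".join(vals) + "\n")


def filter_by_tpm(bundle: DatasetBundle, coding_min: float = 10.0,
                  noncoding_min: float = 2.0) -> DatasetBundle:
    """Keep TSSs whose maximum TPM strictly exceeds the biotype threshold.

    Defaults follow the conservative CAGE-cluster selection: protein-coding
    TSSs above 10 TPM, noncoding above 2 TPM.
    """
    if coding_min <= 0 or noncoding_min <= 0:
        raise ValueError("thresholds must be > 0")
    kept = [tc for tc in bundle.timecourses
            if tc.max_tpm > (coding_min if tc.biotype == "coding" else noncoding_min)]
    logger.info("filter_by_tpm[%s]: kept %d/%d TSSs",
                bundle.dataset_id, len(kept), len(bundle))
    return DatasetBundle(dataset_id=bundle.dataset_id, timecourses=kept,
                         ieg_labels=set(bundle.ieg_labels))


def load_gene_labels(path) -> set:
    """Load a gene label list (one id per line; '#' comments, case preserved)."""
    labels = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                labels.add(entry)
    if not labels:
        logger.warning("gene label file '%s' contains no labels", path)
    return labels


def write_gene_labels(labels, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(labels):
            fh.write(g + "\n")


DEFAULT_CONFIG = {
    "tpm_coding_min": 10.0,
    "tpm_noncoding_min": 2.0,
    "margin": 1.0,                 # decision margin, natural-log units
    "n_live": 100,
    "rate_range": [1e-3, 1.0],
    "slow_factor": 10.0,
    "noise_floor": 0.05,           # normalized units
    "fold_change_floor": 0.5,      # TPM
    "calibration_n": 1000,
    "calibration_noise": None,     # None -> median pooled replicate sd
    "quorum": 7,
    "robust_min_datasets": 7,
    "permissive_min_datasets": 4,
    "n_perm": 1000000,
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Default configuration, optionally updated from a YAML file."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, outputs, counts: dict) -> None:
    """Run manifest: config snapshot, per-stage counts, output checksums."""
    manifest = {
        "config": {k: v for k, v in config.items()},
        "counts": counts,
        "outputs": {str(p): file_checksum(p) for p in outputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def classifications_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "tss_id": r.tss_id, "gene_id": r.gene_id, "dataset_id": r.dataset_id,
            "biotype": r.biotype, "label": r.label, "reason": r.reason or "",
            "tp_mean": r.tp_mean, "tp_sd": r.tp_sd,
            "fold_change": r.fold_change, "peak_variant": r.peak_variant or "",
        }
        for k, v in sorted((r.corrected_logz or {}).items()):
            row[f"logz_corr_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_classifications(records, path) -> None:
    classifications_to_frame(records).to_csv(path, sep="\t", index=False)


def read_classifications(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"tss_id": str, "gene_id": str, "dataset_id": str})
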