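"""Cross-dataset meta-analysis: shared-peak gene sets and IEG enrichment.

Classifications from the per-dataset stage are aggregated to a gene ×
dataset table of peak indicators and earliest peak times; genes peaking in
at least k datasets form nested shared sets (k=7 of 8 is the "robust" set,
k=4 the "permissive" set in an 8-dataset design). Enrichment of a label set
(known immediate early genes) in a group of TSSs is scored by the sample
odds ratio and a two-sided Fisher's exact test on the 2×2 table
[group IEG, group non-IEG; outside IEG, outside non-IEG].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenePeakTable:
    """Gene-level aggregation of peak classifications across datasets."""

    indicator: pd.DataFrame       # genes x datasets, bool: any TSS peaks
    n_peaking: pd.DataFrame       # genes x datasets, int
    earliest_tp: pd.DataFrame     # genes x datasets, float (NaN if no peak)
    biotype: pd.Series            # per gene

    @property
    def datasets(self):
        return list(self.indicator.columns)

    @property
    def genes(self):
        return list(self.indicator.index)

    @property
    def shared_count(self) -> pd.Series:
        """Number of datasets in which each gene has a peaking TSS."""
        return self.indicator.sum(axis=1).astype(int)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for ds in self.datasets:
            parts.append(pd.DataFrame({
                f"{ds}:peak": self.indicator[ds].astype(int),
                f"{ds}:n_peaking_tss": self.n_peaking[ds],
                f"{ds}:earliest_tp": self.earliest_tp[ds],
            }))
        out = pd.concat([pd.DataFrame({"biotype": self.biotype})] + parts, axis=1)
        out.insert(1, "shared_count", self.shared_count)
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def build_gene_peak_table(records_by_dataset: dict) -> GenePeakTable:
    """Aggregate ClassificationRecord collections (one per dataset) by gene.

    A gene absent from a dataset (e.g. below the TPM threshold there) counts
    as not peaking in that dataset. The earliest peak time per gene and
    dataset is the smallest t_p among its peak-classified TSSs.
    """
    if len(records_by_dataset) < 2:
        raise ValueError("need classifications from >= 2 datasets")
    datasets = list(records_by_dataset)
    genes, biotype = {}, {}
    for ds, records in records_by_dataset.items():
        for r in records:
            genes.setdefault(r.gene_id, None)
            biotype.setdefault(r.gene_id, r.biotype)
    gene_list = sorted(genes)
    indicator = pd.DataFrame(False, index=gene_list, columns=datasets)
    n_peaking = pd.DataFrame(0, index=gene_list, columns=datasets)
    earliest = pd.DataFrame(np.nan, index=gene_list, columns=datasets)
    for ds, records in records_by_dataset.items():
        for r in records:
            if r.label != "peak":
                continue
            indicator.loc[r.gene_id, ds] = True
            n_peaking.loc[r.gene_id, ds] += 1
            tp = r.tp_mean
            prev = earliest.loc[r.gene_id, ds]
            if np.isnan(prev) or tp < prev:
                earliest.loc[r.gene_id, ds] = tp
    return GenePeakTable(indicator=indicator, n_peaking=n_peaking,
                         earliest_tp=earliest,
                         biotype=pd.Series(biotype).loc[gene_list])


def shared_set(table: GenePeakTable, min_datasets: int) -> set:
    """Genes with a peak-classified TSS in at least ``min_datasets`` datasets."""
    n_ds = len(table.datasets)
    if not (1 <= min_datasets <= n_ds):
        raise ValueError(f"min_datasets must be in [1, {n_ds}]")
    counts = table.shared_count
    return set(counts.index[counts >= min_datasets])


@dataclass
class EnrichmentResult:
    """2×2 label-set enrichment: sample odds ratio + Fisher exact p."""

    group: str
    a: int                        # group, labelled
    b: int                        # group, unlabelled
    c: int                        # outside, labelled
    d: int                        # outside, unlabelled
    odds_ratio: float
    p_value: float
    continuity_corrected: bool = False

    @property
    def table(self):
        return np.array([[self.a, self.b], [self.c, self.d]])


def ieg_enrichment(group_tss_total: int, group_tss_ieg: int,
                   all_tss_total: int, all_tss_ieg: int,
                   group: str = "") -> EnrichmentResult:
    """Enrichment of labelled (IEG) TSSs in a group vs the remaining TSSs.

    Builds a = group IEG, b = group non-IEG, c = outside IEG, d = outside
    non-IEG and returns the sample odds ratio (a·d)/(b·c) with the two-sided
    Fisher exact p. A zero cell gets the Haldane 0.5 continuity correction
    for the reported OR (flagged); the p-value stays exact.
    """
    if group_tss_ieg > group_tss_total or all_tss_ieg > all_tss_total:
        raise ValueError("labelled counts cannot exceed totals")
    if group_tss_total > all_tss_total or group_tss_ieg > all_tss_ieg:
        raise ValueError("group counts cannot exceed overall counts")
    a = int(group_tss_ieg)
    b = int(group_tss_total - group_tss_ieg)
    c = int(all_tss_ieg - group_tss_ieg)
    d = int(all_tss_total - group_tss_total - c)
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts (negative cell)")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = False
    if b == 0 or c == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(group=group, a=a, b=b, c=c, d=d,
                            odds_ratio=float(orr), p_value=float(p),
                            continuity_corrected=corrected)


def shared_set_enrichment(table: GenePeakTable, records_by_dataset: dict,
                          ieg_labels: set, min_datasets: int) -> EnrichmentResult:
    """TSS-level IEG enrichment of the ≥k-dataset shared gene set.

    Counts peak-classified TSSs (across all datasets) of genes in the shared
    set against peak-classified TSSs of all remaining peaking genes.
    """
    group_genes = shared_set(table, min_datasets)
    group_total = group_ieg = all_total = all_ieg = 0
    for records in records_by_dataset.values():
        for r in records:
            if r.label != "peak":
                continue
            all_total += 1
            is_ieg = r.gene_id in ieg_labels
            all_ieg += is_ieg
            if r.gene_id in group_genes:
                group_total += 1
                group_ieg += is_ieg
    return ieg_enrichment(group_total, group_ieg, all_total, all_ieg,
                          group=f">={min_datasets} datasets")


def per_dataset_class_enrichment(records, ieg_labels: set,
                                 dataset_id: str = "") -> dict:
    """One 2×2 per model class: class TSSs vs all other classified TSSs."""
    classified = [r for r in records if r.classified]
    total = len(classified)
    total_ieg = sum(r.gene_id in ieg_labels for r in classified)
    out = {}
    for cls in ("linear", "decay", "dip", "peak"):
        in_cls = [r for r in classified if r.label == cls]
        if not in_cls:
            continue
        n = len(in_cls)
        n_ieg = sum(r.gene_id in ieg_labels for r in in_cls)
        out[cls] = ieg_enrichment(n, n_ieg, total, total_ieg,
                                  group=f"{dataset_id}:{cls}")
    return out


def enrichment_frame(results) -> pd.DataFrame:
    rows = [{"group": r.group, "group_ieg_tss": r.a,
             "group_other_tss": r.b, "outside_ieg_tss": r.c,
             "outside_other_tss": r.d, "odds_ratio": r.odds_ratio,
             "p_value": r.p_value,
             "continuity_corrected": r.continuity_corrected}
            for r in results]
    return pd.DataFrame(rows)
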