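"""Canonical synthetic studies exercising the pipeline end to end.

Each function freezes one set of study conditions — sample sizes, genome
geometry, mixtures, planted effect sizes — and runs the relevant stages of
the pipeline on data from :mod:`vlincseq.simulate`. They are the package's
reference experiments: the validation suite and the reproduction script
both call them, so the conditions live in exactly one place.

Study conditions (chosen a priori, see docs/methods.md for the arithmetic):

* **Domain recovery** — an 8 Mb chromosome whose trailing 80% is gene
  desert, four planted domains of 60-300 kb at 50x background intergenic
  density, and enough intergenic reads (~2,000) that within-domain read
  spacing (~350 bp) is far below the caller's 5 kb merge gap while
  background spacing (~17 kb) is far above it.
* **Negative control** — the same geometry with multiplier 1 and the
  intergenic read count matched to the positive run's *background* rate,
  i.e. a quiescent desert with no planted signal.
* **Mixture recovery** — 100,000 reads at a 40/35/25
  exonic/intronic/intergenic mixture on a 3 Mb two-chromosome genome.
* **Expression panel** — a 7-tumour/2-normal design (four patients with
  matched pairs plus one unrelated tumour cohort) over 300 features, half
  of them enriched 4x in the main tumour cohort.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import qc
from .models import AlignedRead, Category, PartitionSummary
from .partition import AnnotationIndex, classify_reads, partition_summary
from .simulate import SimulatedDataset, SyntheticConfig, VlincSpec, simulate
from .stats import SampleGroupDesign
from .vlinc import (
    CallerParams,
    RecoveryReport,
    VlincDomain,
    call_domains,
    pool_intergenic_density,
    recover_planted,
)

_CALLER_MIXTURE = {
    Category.RIBOSOMAL: 0.0,
    Category.MITOCHONDRIAL: 0.0,
    Category.EXONIC: 0.3,
    Category.INTRONIC: 0.2,
    Category.INTERGENIC: 0.5,
}


def domain_recovery_config(
    seed: int, multiplier: float = 50.0, n_reads: int = 4_000
) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        chrom_sizes={"chrD": 8_000_000},
        n_genes=12,
        gene_space_fraction=0.2,
        n_reads=n_reads,
        mixture=dict(_CALLER_MIXTURE),
        vlinc_spec=VlincSpec(
            count=4, length_range=(60_000, 300_000), multiplier=multiplier
        ),
    )


@dataclass
class DomainRecoveryResult:
    dataset: SimulatedDataset
    summary: PartitionSummary
    called: List[VlincDomain]
    report: RecoveryReport


def run_domain_recovery(
    seed: int,
    multiplier: float = 50.0,
    n_reads: int = 4_000,
    params: CallerParams = CallerParams(),
) -> DomainRecoveryResult:
    """Simulate planted domains, run QC + classification, call and match."""
    config = domain_recovery_config(seed, multiplier, n_reads)
    dataset = simulate(config)
    informative, _ = qc.run_qc(dataset.reads.placements)
    index = AnnotationIndex(dataset.transcripts, config.chrom_sizes)
    classify_reads(informative, index)
    summary = partition_summary(informative)
    track = pool_intergenic_density(
        {"pooled": (informative, summary.informative_total)}, index, config.chrom_sizes
    )
    called = call_domains(track, params, dataset.transcripts)
    report = recover_planted(called, dataset.vlincs)
    return DomainRecoveryResult(dataset, summary, called, report)


def run_domain_recovery_replicates(
    seed: int, n_replicates: int = 5
) -> List[DomainRecoveryResult]:
    """Independent replicate genomes of the domain-recovery study.

    Recovery accuracy is summarized as the mean Jaccard over *all* planted
    domains across replicates (see :func:`mean_recovery_jaccard`): with
    only four domains per genome, a single stochastic domain split (a
    within-domain read gap exceeding the caller's merge distance) would
    dominate a one-genome mean.
    """
    return [run_domain_recovery(seed + i) for i in range(n_replicates)]


def mean_recovery_jaccard(results: List[DomainRecoveryResult]) -> float:
    """Mean Jaccard over every planted domain in every replicate."""
    values: List[float] = []
    for r in results:
        values.extend(r.report.pairs["jaccard"].fillna(0.0).tolist())
    return float(np.mean(values))


def run_negative_control(seed: int, params: CallerParams = CallerParams()) -> List[VlincDomain]:
    """No planted signal, sparse uniform intergenic background.

    The intergenic read count (~300 over ~6 Mb of desert) matches the
    background rate of the positive run, so any called domain is a false
    positive of the segmentation itself.
    """
    config = domain_recovery_config(seed, multiplier=1.0, n_reads=600)
    dataset = simulate(config)
    informative, _ = qc.run_qc(dataset.reads.placements)
    index = AnnotationIndex(dataset.transcripts, config.chrom_sizes)
    classify_reads(informative, index)
    summary = partition_summary(informative)
    track = pool_intergenic_density(
        {"pooled": (informative, summary.informative_total)}, index, config.chrom_sizes
    )
    return call_domains(track, params, dataset.transcripts)


MIXTURE_TARGET = {
    Category.EXONIC: 0.40,
    Category.INTRONIC: 0.35,
    Category.INTERGENIC: 0.25,
}


def mixture_recovery_config(seed: int, n_reads: int = 100_000) -> SyntheticConfig:
    mixture = {Category.RIBOSOMAL: 0.0, Category.MITOCHONDRIAL: 0.0}
    mixture.update(MIXTURE_TARGET)
    return SyntheticConfig(
        seed=seed,
        chrom_sizes={"chr1": 2_000_000, "chr2": 1_000_000},
        n_genes=30,
        gene_space_fraction=0.5,
        n_reads=n_reads,
        mixture=mixture,
        vlinc_spec=VlincSpec(count=0),
    )


@dataclass
class MixtureRecoveryResult:
    summary: PartitionSummary
    informative: List[AlignedRead]
    true_category: Dict[str, str]  # read_id -> generator label


def run_mixture_recovery(seed: int, n_reads: int = 100_000) -> MixtureRecoveryResult:
    config = mixture_recovery_config(seed, n_reads)
    dataset = simulate(config)
    informative, _ = qc.run_qc(dataset.reads.placements)
    index = AnnotationIndex(dataset.transcripts, config.chrom_sizes)
    classify_reads(informative, index)
    truth = dict(
        zip(dataset.reads.truth["read_id"], dataset.reads.truth["category"])
    )
    return MixtureRecoveryResult(partition_summary(informative), informative, truth)


def expression_panel(
    seed: int,
    n_features: int = 300,
    enrichment: float = 4.0,
) -> Tuple[pd.DataFrame, SampleGroupDesign, np.ndarray]:
    """Synthetic normalized-count table with planted tumour enrichment.

    Seven tumour samples (six from a sarcoma cohort: two matched pairs from
    patients p1/p2 plus singletons from p3/p4; one unrelated leukaemia
    line) and two normals. Half the features carry ``enrichment``-fold
    higher expression in the sarcoma cohort. Counts are lognormal around a
    shared feature profile with patient- and sample-level noise; the
    leukaemia line follows a permuted profile, making it nearly
    uncorrelated with the sarcomas. Returns (table, design, enriched mask).
    """
    rng = np.random.default_rng(seed)
    samples = {
        "sarcoma_p1_primary": ("tumour", "p1", "sarcoma"),
        "sarcoma_p1_metastasis": ("tumour", "p1", "sarcoma"),
        "sarcoma_p2_primary": ("tumour", "p2", "sarcoma"),
        "sarcoma_p2_metastasis": ("tumour", "p2", "sarcoma"),
        "sarcoma_p3_primary": ("tumour", "p3", "sarcoma"),
        "sarcoma_p4_metastasis": ("tumour", "p4", "sarcoma"),
        "leukaemia_line": ("tumour", "p5", "leukaemia"),
        "liver": ("normal", "p6", "normal"),
        "brain": ("normal", "p7", "normal"),
    }
    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_features)
    permuted = rng.permutation(base)
    enriched = np.zeros(n_features, dtype=bool)
    enriched[rng.choice(n_features, n_features // 2, replace=False)] = True
    patient_effect: Dict[str, np.ndarray] = {}
    cols = {}
    for name, (group, patient, cohort) in samples.items():
        if patient not in patient_effect:
            patient_effect[patient] = rng.lognormal(0.0, 0.6, n_features)
        profile = permuted if cohort == "leukaemia" else base
        values = profile * patient_effect[patient] * rng.lognormal(0.0, 0.25, n_features)
        if cohort == "sarcoma":
            values = values * np.where(enriched, enrichment, 1.0)
        cols[name] = values
    table = pd.DataFrame(cols, index=[f"feature_{i + 1}" for i in range(n_features)])
    design = SampleGroupDesign(
        groups={s: g for s, (g, _, _) in samples.items()},
        patients={s: p for s, (_, p, _) in samples.items()},
        cohorts={s: c for s, (_, _, c) in samples.items()},
    )
    return table, design, enriched


def fold_ratio_panel(
    seed: int,
    n_features: int = 200,
    enrichment: float = 4.0,
    samples_per_group: int = 3,
) -> Tuple[pd.DataFrame, SampleGroupDesign, np.ndarray]:
    """Balanced tumour/normal table with a clean planted fold change.

    Equal group sizes make the max-of-group sampling bias identical in
    both groups, so the ratio of the enriched-feature median to the
    background-feature median estimates the planted enrichment directly.
    Counts are tight Gamma draws (shape 50) around the feature mean.
    """
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(50.0), 0.8, n_features)
    enriched = np.zeros(n_features, dtype=bool)
    enriched[rng.choice(n_features, n_features // 2, replace=False)] = True
    shape = 50.0
    cols = {}
    groups = {}
    for i in range(samples_per_group):
        mean = mu * np.where(enriched, enrichment, 1.0)
        cols[f"tumour_{i + 1}"] = rng.gamma(shape, mean / shape)
        groups[f"tumour_{i + 1}"] = "tumour"
    for i in range(samples_per_group):
        cols[f"normal_{i + 1}"] = rng.gamma(shape, mu / shape)
        groups[f"normal_{i + 1}"] = "normal"
    table = pd.DataFrame(cols, index=[f"feature_{i + 1}" for i in range(n_features)])
    return table, SampleGroupDesign(groups=groups), enriched
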