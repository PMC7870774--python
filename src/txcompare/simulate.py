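"""Truth-labelled simulator of gene- and isoform-level RNA-seq counts.

Emulates the two-group study design the analysis assumes: a large reference
("in vivo") group against a small test ("in vitro") group, negative-binomial
gene counts with a mean-dispersion trend and unequal library sizes, a
configurable fraction of DE genes with drawn effect sizes, multi-isoform genes
whose usage percentages sum to 100, and a configurable fraction of DTU genes
in which usage mass is moved off the reference-dominant isoform in the test
group without changing the gene total.

Isoform counts are a multinomial split of the realized gene count, so the
gene total equals the sum of its isoform counts exactly — which is what lets
a gene be non-DE at the gene level yet DTU at the transcript level, the
central phenomenon the pipeline isolates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import GeneCountMatrix, IsoformTable, SampleTable, compute_isoform_percentages

__all__ = ["SimulationConfig", "SimulationResult", "simulate_experiment", "write_rsem_like"]


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulator.

    Defaults mirror the study conditions: 24 reference samples vs 3 test
    replicates, ~2000 genes, library sizes log-uniform over (0.5, 2) million
    reads, a bulk RNA-seq mean-dispersion trend alpha(mu) = 0.05 + 2/mu, 30%
    DE genes with |log2 fold change| >= 1, and 10% DTU genes shifting 30
    usage points off the control-dominant isoform.
    """

    n_genes: int = 2000
    n_control: int = 24
    n_test: int = 3
    #: categorical distribution of isoforms per gene
    isoforms_per_gene: dict = field(
        default_factory=lambda: {1: 0.35, 2: 0.25, 3: 0.20, 4: 0.12, 5: 0.08}
    )
    library_size_range: tuple = (5e5, 2e6)
    #: asymptotic dispersion and 1/mu scale of the trend alpha(mu) = a0 + a1/mu
    dispersion_asymptote: float = 0.05
    dispersion_scale: float = 2.0
    frac_de: float = 0.3
    lfc_sd: float = 1.5
    lfc_min: float = 1.0
    frac_dtu: float = 0.1
    dtu_shift_pct: float = 30.0
    #: log-normal sd of baseline relative expression
    expression_sdlog: float = 1.2
    model_label: str = "INVITRO"
    time_point_h: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_de <= 1 and 0 <= self.frac_dtu <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_control < 2 or self.n_test < 2:
            raise ValueError("need at least 2 samples per group")
        if not (0 <= self.dtu_shift_pct <= 100):
            raise ValueError("dtu_shift_pct must lie in [0, 100]")
        total = sum(self.isoforms_per_gene.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("isoforms_per_gene probabilities must sum to 1")


@dataclass
class SimulationResult:
    genes: GeneCountMatrix
    isoforms: IsoformTable
    samples: SampleTable
    truth: pd.DataFrame  # per gene: is_de, true_lfc, is_dtu, n_isoforms, dominant_isoform, ...
    library_sizes: pd.Series


def _draw_nb(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw: Var = mu + alpha * mu^2."""
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape=shape, scale=mu / shape)
    return rng.poisson(lam).astype(float)


def simulate_experiment(cfg: SimulationConfig) -> SimulationResult:
    """Simulate one two-group experiment; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_samples = cfg.n_control + cfg.n_test

    gene_ids = [f"G{i:05d}" for i in range(n)]
    sample_ids = [f"LIVER_{i + 1:03d}" for i in range(cfg.n_control)] + [
        f"{cfg.model_label}_{i + 1:03d}" for i in range(cfg.n_test)
    ]
    groups = ["control"] * cfg.n_control + ["test"] * cfg.n_test
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "model_label": ["LIVER"] * cfg.n_control + [cfg.model_label] * cfg.n_test,
                "time_point_h": [0] * cfg.n_control + [cfg.time_point_h] * cfg.n_test,
                "replicate_id": [f"r{i + 1}" for i in range(cfg.n_control)]
                + [f"r{i + 1}" for i in range(cfg.n_test)],
            }
        )
    )

    lo, hi = cfg.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    rel = rng.lognormal(mean=0.0, sigma=cfg.expression_sdlog, size=n)
    rel /= rel.sum()

    # isoform structure
    k_values = np.array(sorted(cfg.isoforms_per_gene))
    k_probs = np.array([cfg.isoforms_per_gene[k] for k in k_values], dtype=float)
    n_iso = rng.choice(k_values, size=n, p=k_probs)

    # truth labels: DE and DTU drawn disjointly; DTU needs >= 2 isoforms
    is_de = np.zeros(n, dtype=bool)
    n_de = int(round(cfg.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de[de_idx] = True

    lfc = np.zeros(n)
    if n_de:
        draws = rng.normal(0.0, cfg.lfc_sd, size=n_de)
        while True:
            small = np.abs(draws) < cfg.lfc_min
            if not small.any():
                break
            draws[small] = rng.normal(0.0, cfg.lfc_sd, size=small.sum())
        lfc[de_idx] = draws

    is_dtu = np.zeros(n, dtype=bool)
    multi = np.flatnonzero((n_iso >= 2) & ~is_de)
    n_dtu = int(round(cfg.frac_dtu * n))
    if n_dtu > len(multi):
        raise ValueError("not enough multi-isoform non-DE genes for the requested frac_dtu")
    dtu_idx = rng.choice(multi, size=n_dtu, replace=False)
    is_dtu[dtu_idx] = True

    # dispersions from the trend at the expected mean normalized count
    mu_ref = rel * lib.mean()
    alpha = cfg.dispersion_asymptote + cfg.dispersion_scale / np.maximum(mu_ref, 1e-8)

    # gene counts
    mu = rel[:, None] * lib[None, :]
    test_cols = np.arange(cfg.n_control, n_samples)
    mu[:, test_cols] *= np.power(2.0, lfc)[:, None]
    counts = _draw_nb(rng, mu, np.broadcast_to(alpha[:, None], mu.shape))

    # per-gene usage vectors, sorted so isoform 1 is control-dominant
    iso_rows = []
    iso_counts_rows = []
    parent = []
    truth_rows = []
    for g in range(n):
        k = int(n_iso[g])
        iso_ids = [f"{gene_ids[g]}.T{j + 1}" for j in range(k)]
        if k == 1:
            u_control = np.array([1.0])
            u_test = np.array([1.0])
        else:
            u_control = np.sort(rng.dirichlet(np.full(k, 1.5)))[::-1]
            u_test = u_control.copy()
            if is_dtu[g]:
                shift = cfg.dtu_shift_pct / 100.0
                moved = min(shift, u_control[0])  # infeasible shift floors at 0
                u_test = u_control.copy()
                u_test[0] -= moved
                rest = u_control[1:].sum()
                if rest > 0:
                    u_test[1:] += moved * (u_control[1:] / rest)
                else:
                    u_test[1:] += moved / (k - 1)
        parent.extend([gene_ids[g]] * k)
        iso_rows.append(iso_ids)
        gene_counts = counts[g]
        split = np.empty((k, n_samples))
        for j in range(n_samples):
            usage = u_test if groups[j] == "test" else u_control
            split[:, j] = rng.multinomial(int(gene_counts[j]), usage)
        iso_counts_rows.append(split)
        truth_rows.append(
            {
                "gene_id": gene_ids[g],
                "is_de": bool(is_de[g]),
                "true_lfc": float(lfc[g]),
                "is_dtu": bool(is_dtu[g]),
                "n_isoforms": k,
                "dominant_isoform": iso_ids[0],
                "control_usage": ",".join(f"{u:.6f}" for u in u_control),
                "test_usage": ",".join(f"{u:.6f}" for u in u_test),
            }
        )

    iso_ids_flat = [i for ids in iso_rows for i in ids]
    iso_counts = pd.DataFrame(
        np.vstack(iso_counts_rows), index=iso_ids_flat, columns=sample_ids
    )
    iso_table = compute_isoform_percentages(
        IsoformTable(iso_counts, pd.Series(parent, index=iso_ids_flat))
    )

    # gene matrix from the isoform split keeps gene totals = isoform sums exactly;
    # (the NB draw itself is integer, so the totals are the NB counts)
    gene_counts_frame = iso_table.gene_totals().reindex(gene_ids)
    gene_matrix = GeneCountMatrix(gene_counts_frame)

    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return SimulationResult(
        genes=gene_matrix,
        isoforms=iso_table,
        samples=samples,
        truth=truth,
        library_sizes=pd.Series(lib, index=sample_ids, name="library_size"),
    )


def write_rsem_like(result: SimulationResult, out_dir: str | Path) -> dict:
    """Write per-sample ``.genes.results`` / ``.isoforms.results``-style files,
    the sample sheet and the truth table. Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {"genes": [], "isoforms": []}
    for sample in result.genes.sample_ids:
        gpath = out_dir / f"{sample}.genes.results"
        pd.DataFrame(
            {
                "gene_id": result.genes.gene_ids,
                "expected_count": result.genes.counts[sample].to_numpy(),
            }
        ).to_csv(gpath, sep="\t", index=False)
        ipath = out_dir / f"{sample}.isoforms.results"
        pd.DataFrame(
            {
                "transcript_id": result.isoforms.isoform_ids,
                "gene_id": result.isoforms.parent_gene.to_numpy(),
                "expected_count": result.isoforms.counts[sample].to_numpy(),
                "IsoPct": result.isoforms.usage_pct[sample].to_numpy(),
            }
        ).to_csv(ipath, sep="\t", index=False)
        paths["genes"].append(gpath)
        paths["isoforms"].append(ipath)
    sheet = out_dir / "sample_sheet.tsv"
    result.samples.frame.to_csv(sheet, sep="\t", index=False)
    truth = out_dir / "truth.tsv"
    result.truth.to_csv(truth, sep="\t")
    paths["sample_sheet"] = sheet
    paths["truth"] = truth
    return paths
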