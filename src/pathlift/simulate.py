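"""Deterministic generators for synthetic pathway hierarchies and
planted-signal multi-omics data.

The generator emulates the shape of a pan-cancer tumour-recurrence cohort:
sparse binary somatic-mutation indicators, integer copy-number scores in
[-2, 2], and a roughly 1:2.8 class imbalance (134 recurrent / 371
non-recurrent out of 505).  A small set of "informative" genes carries the
planted signal: their mutation rate is multiplied by ``1 + effect_size`` in
positive samples and their copy-number mean is shifted by ``+effect_size``.
Everything is a pure function of the spec — the same spec yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import PathwayHierarchy, layerize
from .omics import OmicsMatrix

__all__ = ["SyntheticSpec", "make_hierarchy", "make_omics", "make_study",
           "write_hierarchy_files"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe the package's reference study conditions: a five-layer
    hierarchy of 19 pathways over 64 genes, 505 samples at 134/505 positive
    fraction, mutation background rate 5%, copy-number noise SD 0.6, and a
    strong planted effect (mutation rate doubled, +1 copy-number mean shift)
    in 8 informative genes, one per leaf pathway.  The +1 shift keeps the
    clipped [-2, 2] copy-number scale unsaturated so each informative gene is
    individually informative but not sufficient on its own.
    """

    layer_widths: tuple[int, ...] = (8, 5, 3, 2, 1)
    edge_density: float = 0.5
    genes_per_leaf: int = 8
    n_samples: int = 505
    positive_fraction: float = 134 / 505
    n_informative: int = 8
    informative_genes: list[str] | None = None
    effect_size: float = 1.0
    snv_background_rate: float = 0.05
    cnv_noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if any(w < 1 for w in self.layer_widths):
            raise ValueError("all layer widths must be >= 1")


def make_hierarchy(spec: SyntheticSpec) -> tuple[list[tuple[str, str]], dict[str, set[str]]]:
    """Random layered DAG honouring the layer widths; no node is prunable.

    Every node below the top layer gets at least one successor and every
    node above the bottom layer at least one predecessor, and all edges
    connect consecutive layers, so ``layerize`` retains the graph verbatim.
    Returns ``(edges, gene_sets)``.
    """
    rng = np.random.default_rng(spec.seed)
    widths = spec.layer_widths
    names = [[f"PW{l + 1}_{j:02d}" for j in range(w)] for l, w in enumerate(widths)]
    edges: list[tuple[str, str]] = []
    for l in range(len(widths) - 1):
        lower, upper = names[l], names[l + 1]
        has_pred = {u: False for u in upper}
        for c in lower:
            succ = [u for u in upper if rng.random() < spec.edge_density]
            if not succ:
                succ = [upper[rng.integers(0, len(upper))]]
            for u in succ:
                edges.append((c, u))
                has_pred[u] = True
        for u in upper:
            if not has_pred[u]:
                edges.append((lower[rng.integers(0, len(lower))], u))
    gene_sets: dict[str, set[str]] = {}
    g = 0
    for leaf in names[0]:
        gene_sets[leaf] = {f"G{g + i + 1:04d}" for i in range(spec.genes_per_leaf)}
        g += spec.genes_per_leaf
    return edges, gene_sets


def write_hierarchy_files(spec: SyntheticSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the relation TSV and GMT in the dialects the parsers read."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges, gene_sets = make_hierarchy(spec)
    rel = out_dir / "relations.tsv"
    with rel.open("w", newline="\n") as fh:
        fh.write("# child\tparent\n")
        for c, p in sorted(edges):
            fh.write(f"{c}\t{p}\n")
    gmt = out_dir / "gene_sets.gmt"
    with gmt.open("w", newline="\n") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tsynthetic pathway\t{genes}\n")
    return rel, gmt


def _informative(spec: SyntheticSpec, gene_sets: dict[str, set[str]]) -> list[str]:
    if spec.informative_genes is not None:
        vocab = set().union(*gene_sets.values())
        missing = [g for g in spec.informative_genes if g not in vocab]
        if missing:
            raise ValueError(f"informative gene(s) not in hierarchy vocabulary: {missing}")
        return list(spec.informative_genes)
    # one gene per leaf pathway, round-robin, until n_informative
    leaves = sorted(gene_sets)
    chosen: list[str] = []
    depth = 0
    while len(chosen) < spec.n_informative:
        for leaf in leaves:
            genes = sorted(gene_sets[leaf])
            if depth < len(genes):
                chosen.append(genes[depth])
                if len(chosen) == spec.n_informative:
                    break
        depth += 1
        if depth > max(len(v) for v in gene_sets.values()):
            raise ValueError("n_informative exceeds the gene vocabulary")
    return chosen


def make_omics(
    spec: SyntheticSpec,
    gene_sets: dict[str, set[str]] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.Series]:
    """Generate (SNV, CNV, labels) with a planted signal in positive samples.

    SNV features are Bernoulli with the background rate, multiplied by
    ``1 + effect_size`` (capped at 0.95) for informative genes in positives.
    CNV features are round(Normal(mu, sd)) clipped to [-2, 2] with ``mu = 0``
    except ``mu = effect_size`` for informative genes in positives.  The
    number of positive labels equals ``round(n * positive_fraction)`` exactly.
    """
    if gene_sets is None:
        _, gene_sets = make_hierarchy(spec)
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(set().union(*gene_sets.values()))
    informative = set(_informative(spec, gene_sets))

    n = spec.n_samples
    n_pos = int(round(n * spec.positive_fraction))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1
    sample_ids = [f"SA{i + 1:04d}" for i in range(n)]

    base = spec.snv_background_rate
    boosted = min(0.95, base * (1.0 + spec.effect_size))
    snv = np.zeros((n, len(genes)), dtype=int)
    cnv = np.zeros((n, len(genes)), dtype=int)
    for j, gname in enumerate(genes):
        info = gname in informative
        rate = np.where(labels == 1, boosted if info else base, base)
        snv[:, j] = rng.random(n) < rate
        mu = np.where((labels == 1) & info, spec.effect_size, 0.0)
        vals = np.rint(rng.normal(mu, spec.cnv_noise_sd)).astype(int)
        cnv[:, j] = np.clip(vals, -2, 2)

    snv_df = pd.DataFrame(snv, index=sample_ids, columns=[f"{g}|SNV" for g in genes])
    cnv_df = pd.DataFrame(cnv, index=sample_ids, columns=genes)
    labels_s = pd.Series(labels, index=sample_ids, name="label")

    snv_m = OmicsMatrix(values=snv_df.astype(float),
                        feature_gene={f"{g}|SNV": g for g in genes},
                        omics_type="SNV", labels=labels_s)
    cnv_m = OmicsMatrix(values=cnv_df.astype(float),
                        feature_gene={g: g for g in genes},
                        omics_type="CNV", labels=labels_s)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        snv_df.rename_axis("sample_id").to_csv(out_dir / "snv.csv")
        cnv_df.rename_axis("sample_id").to_csv(out_dir / "cnv.csv")
        labels_s.rename_axis("sample_id").reset_index().to_csv(out_dir / "labels.csv", index=False)
    return snv_m, cnv_m, labels_s


def make_study(spec: SyntheticSpec) -> tuple[PathwayHierarchy, OmicsMatrix, OmicsMatrix, pd.Series, list[str]]:
    """Hierarchy + omics + labels + planted gene list, in memory."""
    edges, gene_sets = make_hierarchy(spec)
    hier = layerize(edges, gene_sets, depth=len(spec.layer_widths))
    snv, cnv, labels = make_omics(spec, gene_sets)
    return hier, snv, cnv, labels, _informative(spec, gene_sets)
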