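"""Multi-omics preprocessing: noise filtering, CNV sign-splitting, chi-square
feature selection and assembly of the model input matrix.

The input dialect is gene-level matrices (samples x features, CSV/TSV with
the sample id in the first column).  Somatic mutation indicators (SNV) are
binary; copy-number scores are GISTIC-style integers in [-2, 2] and are
split into non-negative amplification (AMP_CNV) and deletion (DEL_CNV)
magnitudes so that the non-negative chi-square feature score applies
uniformly to every block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import chi2 as _sk_chi2

from .hierarchy import MaskStack

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "read_omics_csv",
    "read_labels_csv",
    "split_cnv",
    "filter_noise",
    "chi2_scores",
    "chi2_select",
    "assemble_input",
]

OMICS_TYPES = ("SNV", "AMP_CNV", "DEL_CNV")


@dataclass
class OmicsMatrix:
    """One omics block: a samples x features value matrix plus feature metadata."""

    values: pd.DataFrame                      # index = sample ids, columns = feature ids
    feature_gene: dict[str, str]              # feature id -> gene symbol
    omics_type: str | dict[str, str]          # block-wide or per-feature
    labels: pd.Series | None = None           # binary, indexed by sample id

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def type_of(self, feature: str) -> str:
        if isinstance(self.omics_type, dict):
            return self.omics_type[feature]
        return self.omics_type

    def feature_table(self) -> list[tuple[str, str, str]]:
        """(feature_id, gene, omics_type) rows, in column order."""
        return [(f, self.feature_gene[f], self.type_of(f)) for f in self.feature_ids]


def read_omics_csv(path: str | Path, omics_type: str, sep: str | None = None) -> OmicsMatrix:
    """Load a samples x features matrix; header features are ``GENE`` or ``GENE|TYPE``."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    feature_gene = {f: str(f).split("|")[0].upper() for f in df.columns}
    return OmicsMatrix(values=df, feature_gene=feature_gene, omics_type=omics_type)


def read_labels_csv(path: str | Path) -> pd.Series:
    """Load a (sample_id, label) CSV; labels must be 0/1."""
    df = pd.read_csv(path)
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="label")
    vals = set(np.unique(s.to_numpy()))
    if not vals <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(vals)}")
    return s.astype(int)


def split_cnv(cnv: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Split signed copy-number scores into amplification and deletion magnitudes.

    ``amp = max(v, 0)`` and ``del = max(-v, 0)``, so ``amp - del`` recovers the
    input and ``amp + del = |v|`` (total absolute dosage is conserved).
    Feature ids get ``|AMP_CNV`` / ``|DEL_CNV`` suffixes.
    """
    vals = cnv.values
    if not np.issubdtype(vals.to_numpy().dtype, np.number):
        raise ValueError("CNV matrix contains non-numeric entries")

    def _mk(arr: np.ndarray, suffix: str) -> OmicsMatrix:
        cols = [f"{cnv.feature_gene[f]}|{suffix}" for f in vals.columns]
        df = pd.DataFrame(arr, index=vals.index, columns=cols)
        fg = {c: cnv.feature_gene[f] for c, f in zip(cols, vals.columns)}
        return OmicsMatrix(values=df, feature_gene=fg, omics_type=suffix, labels=cnv.labels)

    a = np.maximum(vals.to_numpy(dtype=float), 0.0)
    d = np.maximum(-vals.to_numpy(dtype=float), 0.0)
    return _mk(a, "AMP_CNV"), _mk(d, "DEL_CNV")


def filter_noise(
    x: OmicsMatrix, min_variance: float = 0.0, max_missing_frac: float = 0.2
) -> OmicsMatrix:
    """Drop noisy features and zero-impute what remains.

    A feature is dropped when its variance (missing values ignored) falls
    below ``min_variance`` — with the convention that ``min_variance = 0``
    still drops exact constants — or when its missing fraction exceeds
    ``max_missing_frac``.  Surviving missing values are imputed to 0, the
    same baseline the attribution reference uses (absence of aberration).
    """
    vals = x.values
    arr = vals.to_numpy(dtype=float)
    miss = np.isnan(arr)
    miss_frac = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        var = np.nanvar(arr, axis=0)
    var = np.where(np.isnan(var), 0.0, var)
    # exact constants (var == 0) are always noise, even at min_variance = 0
    keep = (miss_frac <= max_missing_frac) & (var >= min_variance) & (var > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_noise: dropped %d/%d features", n_drop, len(keep))
    if not keep.any():
        raise ValueError("all features dropped by noise filter")
    kept_cols = [c for c, k in zip(vals.columns, keep) if k]
    out = vals[kept_cols].fillna(0.0)
    fg = {c: x.feature_gene[c] for c in kept_cols}
    ot = x.omics_type if isinstance(x.omics_type, str) else {c: x.omics_type[c] for c in kept_cols}
    return OmicsMatrix(values=out, feature_gene=fg, omics_type=ot, labels=x.labels)


def chi2_scores(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square feature score for non-negative features against binary labels.

    Per feature, observed per-class value sums are compared with the sums
    expected under class independence (class priors times the grand total);
    the statistic is referred to a chi-square distribution with one degree
    of freedom (two classes).  Returns ``(statistics, p_values)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if (values < 0).any():
        raise ValueError("chi-square scoring requires non-negative feature values")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    stat, p = _sk_chi2(values, labels)
    # constant-zero features yield nan in sklearn; score them as no-signal
    stat = np.where(np.isnan(stat), 0.0, stat)
    p = np.where(np.isnan(p), 1.0, p)
    return stat, p


def chi2_select(x: OmicsMatrix, labels: pd.Series | np.ndarray, k: int = 3000) -> OmicsMatrix:
    """Retain the top-``k`` features of one omics block by chi-square P-value.

    Ranking is by ascending P-value (df = 1), ties broken by descending
    statistic then lexicographic feature id.  ``k`` larger than the feature
    count keeps everything (logged).
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(x.values.index).to_numpy()
    labels = np.asarray(labels)
    stat, p = chi2_scores(x.values.to_numpy(dtype=float), labels)
    feats = list(x.values.columns)
    order = sorted(range(len(feats)), key=lambda i: (p[i], -stat[i], feats[i]))
    if k >= len(feats):
        if k > len(feats):
            logger.warning("chi2_select: k=%d exceeds %d features; keeping all", k, len(feats))
        chosen = order
    else:
        chosen = order[:k]
    cols = [feats[i] for i in chosen]
    fg = {c: x.feature_gene[c] for c in cols}
    ot = x.omics_type if isinstance(x.omics_type, str) else {c: x.omics_type[c] for c in cols}
    return OmicsMatrix(values=x.values[cols], feature_gene=fg, omics_type=ot, labels=x.labels)


def assemble_input(
    blocks: list[OmicsMatrix], masks: MaskStack
) -> tuple[np.ndarray, list[str], MaskStack]:
    """Concatenate omics blocks and align columns to the mask stack's feature order.

    Blocks are joined on the intersection of their sample ids (logged when
    samples drop).  Features absent from ``masks.node_index['feature']`` are
    discarded; the returned matrix's column order equals the input-mask row
    order exactly.  Returns ``(X, sample_ids, masks)``.
    """
    if not blocks:
        raise ValueError("no omics blocks given")
    samples = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        samples &= set(b.sample_ids)
    if not samples:
        raise ValueError("empty sample intersection across omics blocks")
    n_max = max(len(b.sample_ids) for b in blocks)
    if len(samples) < n_max:
        logger.info("assemble_input: %d sample(s) dropped by intersection", n_max - len(samples))
    sample_order = [s for s in blocks[0].sample_ids if s in samples]

    col_map: dict[str, np.ndarray] = {}
    for b in blocks:
        sub = b.values.loc[sample_order]
        for f in b.feature_ids:
            col_map[f] = sub[f].to_numpy(dtype=float)

    feat_order = masks.node_index["feature"]
    missing = [f for f in feat_order if f not in col_map]
    if missing:
        raise ValueError(f"mask expects features absent from blocks, e.g. {missing[:3]}")
    unused = len(col_map) - len(feat_order)
    if unused:
        logger.info("assemble_input: %d feature(s) not in mask dropped", unused)
    X = np.column_stack([col_map[f] for f in feat_order])
    return X, sample_order, masks
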