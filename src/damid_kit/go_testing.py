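"""GATC-density-bias-corrected gene-ontology over-representation testing.

GATC motifs are unevenly spread across the genome, so genes flanked by
more GATC regions have more chances to be tagged by a peak.  Uncorrected
hypergeometric (Fisher-style) category tests therefore over-report terms
populated by GATC-dense genes.  The correction mirrors the detection-bias
framework used for length bias in RNA-seq category testing:

1. each gene's *bias value* is the number of GATC regions within a
   window (2 kb by default) of the gene span;
2. a monotone probability weighting function (PWF) — the probability
   that a gene with a given bias value is significant — is fitted by
   isotonic regression of the significance indicator on the bias;
3. each category's over-representation p-value is the upper tail of a
   Wallenius noncentral hypergeometric distribution whose odds ratio is
   formed from the mean PWF weight inside versus outside the category.

A Monte-Carlo mode draws significant-gene sets by weighted sampling
without replacement (per-gene odds), providing a reference answer for
the two-group Wallenius approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .dm_testing import bh_adjust
from .gatc_index import GatcRegion, InputError
from .gene_annotation import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_BIAS_WINDOW_BP = 2000
_W_FLOOR = 1e-6


@dataclass
class GoGeneRecord:
    gene_id: str
    is_significant: bool
    bias: int

    def __post_init__(self) -> None:
        if self.bias < 0:
            raise ValueError("bias must be non-negative")


@dataclass
class PwfFit:
    """Per-gene fitted probabilities of significance given the bias value."""

    gene_ids: list[str]
    weights: np.ndarray = field(repr=False)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.gene_ids)


def compute_bias(
    genes: list[GeneModel],
    regions: list[GatcRegion],
    window_bp: int = DEFAULT_BIAS_WINDOW_BP,
) -> dict[str, int]:
    """Number of GATC regions overlapping [gene.start - window, gene.end + window)."""
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    bias = {}
    for g in genes:
        tree = trees.get(g.chrom)
        lo = max(0, g.start - window_bp)
        hi = g.end + window_bp
        bias[g.gene_id] = len(tree.overlap(lo, hi)) if tree is not None else 0
    return bias


def make_records(
    peak_genes: pd.DataFrame, genes: list[GeneModel], bias: dict[str, int]
) -> list[GoGeneRecord]:
    """Build the gene table feeding the PWF: significance from the peak-gene map."""
    sig_ids = set(peak_genes.loc[peak_genes["gene_id"] != "none", "gene_id"])
    return [
        GoGeneRecord(g.gene_id, g.gene_id in sig_ids, bias.get(g.gene_id, 0))
        for g in genes
    ]


def fit_pwf(records: list[GoGeneRecord]) -> PwfFit:
    """Monotone fit of P(significant | bias) by isotonic regression.

    Weights are floored/capped away from 0 and 1 and rescaled so their
    mean equals the observed significant fraction.  Requires at least
    two distinct bias values and both significant and non-significant
    genes.
    """
    bias = np.array([r.bias for r in records], dtype=float)
    sig = np.array([r.is_significant for r in records], dtype=float)
    if len(np.unique(bias)) < 2:
        # constant bias: every gene gets the overall significant fraction
        frac = float(sig.mean())
        if frac in (0.0, 1.0):
            raise InputError("degenerate input: all genes share one significance state")
        w = np.full(len(records), frac)
        return PwfFit([r.gene_id for r in records], w)
    if sig.sum() == 0 or sig.sum() == len(records):
        raise InputError("degenerate input: all genes share one significance state")

    iso = IsotonicRegression(y_min=_W_FLOOR, y_max=1 - _W_FLOOR, out_of_bounds="clip")
    order = np.argsort(bias, kind="stable")
    iso.fit(bias[order], sig[order])
    w = iso.predict(bias)
    # rescale so mean weight matches the observed significant fraction
    w = np.clip(w * sig.mean() / w.mean(), _W_FLOOR, 1 - _W_FLOOR)
    return PwfFit([r.gene_id for r in records], w)


def _wallenius_upper_tail(
    n_total: int, n_in_cat: int, n_draws: int, odds: float, k: int
) -> float:
    """P(X >= k) for Wallenius noncentral hypergeometric."""
    if k <= 0:
        return 1.0
    upper = min(n_in_cat, n_draws)
    if k > upper:
        return 0.0
    if np.isclose(odds, 1.0):
        return float(stats.hypergeom.sf(k - 1, n_total, n_in_cat, n_draws))
    d = stats.nchypergeom_wallenius(n_total, n_in_cat, n_draws, odds)
    return float(np.clip(d.sf(k - 1), 0.0, 1.0))


def test_categories(
    records: list[GoGeneRecord],
    pwf: PwfFit,
    cat_map: dict[str, set[str]],
    mc_draws: int = 0,
    rng: np.random.Generator | None = None,
    corrected: bool = True,
) -> pd.DataFrame:
    """Per-category over-representation p-values with BH FDR.

    For each term the odds ratio is
    ``[mean w in / (1 - mean w in)] / [mean w out / (1 - mean w out)]``
    and the p-value is the Wallenius upper tail of observing at least the
    seen number of significant genes in the category, drawing the total
    number of significant genes from all genes.  ``mc_draws > 0``
    switches to the Monte-Carlo estimate via weighted sampling without
    replacement.  ``corrected=False`` forces odds 1 (plain hypergeometric).
    """
    ids = [r.gene_id for r in records]
    id_set = set(ids)
    sig = np.array([r.is_significant for r in records])
    w = pwf.as_series().reindex(ids).to_numpy()
    n_total = len(ids)
    n_draws = int(sig.sum())
    idx = {g: i for i, g in enumerate(ids)}

    rows = []
    for term, members in sorted(cat_map.items()):
        known = members & id_set
        dropped = len(members) - len(known)
        if dropped:
            logger.info("term %s: %d gene(s) outside the universe dropped", term, dropped)
        if not known:
            logger.info("term %s skipped: no genes in universe", term)
            continue
        member_idx = np.array(sorted(idx[g] for g in known))
        n_in = len(member_idx)
        k = int(sig[member_idx].sum())

        if corrected:
            w_in = float(w[member_idx].mean())
            mask = np.ones(n_total, dtype=bool)
            mask[member_idx] = False
            w_out = float(w[mask].mean()) if mask.any() else w_in
            odds = (w_in / (1 - w_in)) / (w_out / (1 - w_out))
        else:
            odds = 1.0

        if mc_draws > 0:
            p_over = _mc_upper_tail(w if corrected else np.full(n_total, 0.5),
                                    member_idx, n_draws, k, mc_draws, rng)
        else:
            p_over = _wallenius_upper_tail(n_total, n_in, n_draws, odds, k)
        rows.append(
            {
                "term_id": term,
                "n_in_cat": n_in,
                "n_sig_in_cat": k,
                "odds": odds,
                "p_over": max(p_over, np.finfo(float).tiny),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p_over"].to_numpy())
        out = out.sort_values("p_over", kind="stable").reset_index(drop=True)
    return out


def _mc_upper_tail(
    w: np.ndarray,
    member_idx: np.ndarray,
    n_draws: int,
    k: int,
    n_sim: int,
    rng: np.random.Generator | None,
) -> float:
    """Monte-Carlo P(X >= k) by weighted sampling without replacement.

    Sequential sampling with probability proportional to per-gene odds is
    realized with the exponential-race equivalence: draw Exp(1)/odds keys
    and take the ``n_draws`` smallest.
    """
    if k <= 0:
        return 1.0
    rng = rng or np.random.default_rng()
    odds = w / (1.0 - w)
    member_mask = np.zeros(len(w), dtype=bool)
    member_mask[member_idx] = True
    hits = 0
    batch = max(1, int(5e7 // max(len(w), 1)))
    done = 0
    while done < n_sim:
        m = min(batch, n_sim - done)
        keys = rng.exponential(size=(m, len(w))) / odds[None, :]
        chosen = np.argpartition(keys, n_draws - 1, axis=1)[:, :n_draws]
        counts = member_mask[chosen].sum(axis=1)
        hits += int((counts >= k).sum())
        done += m
    # add-one smoothing keeps the estimate in (0, 1]
    return (hits + 1) / (n_sim + 1)


def read_categories(path) -> dict[str, set[str]]:
    """Read a two-column TSV (term_id, gene_id) into a term -> gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["term_id", "gene_id"])
    if df.iloc[0]["term_id"] in ("term_id", "term"):  # tolerate a header row
        df = df.iloc[1:]
    cat_map: dict[str, set[str]] = {}
    for term, gene in zip(df["term_id"], df["gene_id"]):
        cat_map.setdefault(str(term), set()).add(str(gene))
    return cat_map
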