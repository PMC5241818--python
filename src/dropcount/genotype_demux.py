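"""Genotype-free assignment of cells to one or two genomes.

Per-cell reference/alternate UMI counts at transcribed SNV sites are
modelled as a mixture of K genomes (K in {1, 2}).  At each site a
genome carries one of three genotypes — R/R, R/A or A/A — and the
alternate-allele count in a cell is binomial with success probability
eps, 0.5 or 1 - eps respectively, where eps is a fixed base error rate
(0.1% by default).  Inference of the cell-to-genome assignments and
the K genotype vectors uses a Gibbs sampler; the label-switching
symmetry of the K=2 posterior is removed by Stephens' decision-theoretic
relabelling.  K=2 is selected over K=1 only when at least 90% of cells
have an assignment posterior above 75%; otherwise the mixture fraction
is declared below the detection level.

The module also contains the simpler SNV-based cell labelling used for
two-cell-line mixtures (enriched-SNV fractions with 0.2/0.8 bands).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln, logsumexp

from .io_formats import AlleleCountPair

logger = logging.getLogger(__name__)

#: Genotypes in index order: homozygous reference, het, homozygous alt.
GENOTYPES = ("R/R", "R/A", "A/A")

_P_CLIP = 1e-12


@dataclass
class MixtureParams:
    """Tunables of the binomial-mixture demultiplexer.

    error_rate
        Fixed per-base error probability eps; the alt-allele binomial
        probability is eps (R/R), 0.5 (R/A) or 1 - eps (A/A).
    n_iterations / n_burnin
        Gibbs sweeps per chain and how many are discarded.
    n_chains
        Independent chains; each is relabelled and aligned, and chains
        whose held fit quality matches the best chain are pooled.
    init / misfit_seed_fraction
        Chain initialisation.  "misfit" (default) warm-starts the
        second genome with the ``misfit_seed_fraction`` of cells worst
        explained by the pooled single-genome genotypes — a split-move
        style start that lets a genuine minor population nucleate
        while a spurious seed dissolves back into the symmetric state.
        "random" assigns cells to genomes uniformly.
    cell_fraction_threshold / posterior_threshold
        The K=2 selection rule: choose K=2 iff at least
        ``cell_fraction_threshold`` of cells have an assignment
        posterior strictly above ``posterior_threshold``.
    """

    error_rate: float = 0.001
    n_iterations: int = 500
    n_burnin: int = 200
    n_chains: int = 2
    seed: int = 0
    cell_fraction_threshold: float = 0.90
    posterior_threshold: float = 0.75
    init: str = "misfit"
    misfit_seed_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        for t in (self.cell_fraction_threshold, self.posterior_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError("selection thresholds must be in (0, 1)")
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")


@dataclass
class GenotypeModel:
    """Posterior summaries of one fitted mixture model."""

    K: int
    cells: list[str]
    site_keys: list[tuple]
    genotype_posterior: np.ndarray      # K x n_sites x 3, rows sum to 1
    cell_posterior: np.ndarray          # n_cells x K, rows sum to 1
    diagnostics: dict = field(default_factory=dict)

    @property
    def map_genotypes(self) -> np.ndarray:
        """K x n_sites MAP genotype indices."""
        return np.argmax(self.genotype_posterior, axis=2)

    @property
    def map_genome(self) -> np.ndarray:
        return np.argmax(self.cell_posterior, axis=1)

    @property
    def map_posterior(self) -> np.ndarray:
        return np.max(self.cell_posterior, axis=1)

    @property
    def genome_fractions(self) -> np.ndarray:
        """Fraction of cells MAP-assigned to each genome."""
        counts = np.bincount(self.map_genome, minlength=self.K)
        return counts / max(len(self.cells), 1)

    @property
    def minor_fraction(self) -> float:
        """Mixture fraction of the smaller genome (0 for K=1)."""
        return float(self.genome_fractions.min()) if self.K > 1 else 0.0

    def genotype_dict(self, genome: int = 0) -> dict[tuple, int]:
        """MAP genotype per site key for one genome."""
        gt = self.map_genotypes[genome]
        return {key: int(g) for key, g in zip(self.site_keys, gt)}


def _alt_probs(eps: float) -> np.ndarray:
    return np.array([eps, 0.5, 1.0 - eps])


def site_log_likelihood(r: int, a: int, genotype: int | str, error_rate: float = 0.001) -> float:
    """log Binomial(a; n=r+a, p(genotype)) with p in {eps, 1/2, 1-eps}."""
    if isinstance(genotype, str):
        genotype = GENOTYPES.index(genotype)
    if r < 0 or a < 0:
        raise ValueError("counts must be non-negative")
    p = _alt_probs(error_rate)[genotype]
    if r + a == 0:
        return 0.0
    coeff = gammaln(r + a + 1) - gammaln(a + 1) - gammaln(r + 1)
    return float(coeff + a * np.log(p) + r * np.log1p(-p))


def _sparse_union_entries(pair: AlleleCountPair) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """COO arrays (cell_idx, site_idx, ref, alt) over covered entries."""
    cov = (pair.ref_counts + pair.alt_counts).tocoo()
    if cov.nnz == 0:
        raise ValueError("no covered (cell, site) entries")
    rows, cols = cov.row, cov.col
    ref = np.asarray(pair.ref_counts.tocsr()[rows, cols]).ravel()
    alt = np.asarray(pair.alt_counts.tocsr()[rows, cols]).ravel()
    return rows, cols, ref, alt


def _entry_logliks(ref: np.ndarray, alt: np.ndarray, eps: float) -> np.ndarray:
    """nnz x 3 genotype log-likelihoods (binomial coefficient omitted:
    it is constant across genotypes and cancels in every conditional)."""
    p = _alt_probs(eps)
    return alt[:, None] * np.log(p)[None, :] + ref[:, None] * np.log1p(-p)[None, :]


def _fit_k1(pair: AlleleCountPair, params: MixtureParams) -> GenotypeModel:
    """K=1 posterior in closed form.

    With a single genome the site genotypes are conditionally
    independent given the pooled counts, so the Gibbs sampler's
    stationary distribution is available exactly: the per-site
    genotype posterior is the normalised pooled likelihood under a
    uniform prior.
    """
    rows, cols, ref, alt = _sparse_union_entries(pair)
    L = _entry_logliks(ref, alt, params.error_rate)
    n_sites = len(pair.sites)
    site_ll = np.zeros((n_sites, 3))
    for g in range(3):
        site_ll[:, g] = np.bincount(cols, weights=L[:, g], minlength=n_sites)
    log_post = site_ll - logsumexp(site_ll, axis=1, keepdims=True)
    post = np.exp(log_post)
    return GenotypeModel(
        K=1,
        cells=list(pair.cells),
        site_keys=list(pair.sites),
        genotype_posterior=post[None, :, :],
        cell_posterior=np.ones((len(pair.cells), 1)),
        diagnostics={"method": "exact"},
    )


def _misfit_seed(
    rows: np.ndarray,
    cols: np.ndarray,
    L: np.ndarray,
    n_cells: int,
    n_sites: int,
    fraction: float,
) -> np.ndarray:
    """Initial assignment seeding genome 1 with the worst-fit cells.

    The misfit of a cell is the gap between its best achievable
    log-likelihood (per-site MAP given its own counts) and its
    log-likelihood under the pooled single-genome MAP genotypes; cells
    of a hidden second donor concentrate at the top of this ranking.
    The top ``fraction`` of cells start in genome 1, the rest in 0.
    """
    site_ll = np.zeros((n_sites, 3))
    for g in range(3):
        site_ll[:, g] = np.bincount(cols, weights=L[:, g], minlength=n_sites)
    pooled_map = site_ll.argmax(axis=1)
    ll_pooled = np.bincount(
        rows, weights=L[np.arange(len(rows)), pooled_map[cols]], minlength=n_cells
    )
    ll_best = np.bincount(rows, weights=L.max(axis=1), minlength=n_cells)
    deficit = ll_best - ll_pooled
    k = max(1, int(round(fraction * n_cells)))
    z = np.zeros(n_cells, dtype=np.int64)
    z[np.argsort(-deficit)[:k]] = 1
    return z


def _gibbs_chain(
    rows: np.ndarray,
    cols: np.ndarray,
    L: np.ndarray,
    n_cells: int,
    n_sites: int,
    params: MixtureParams,
    rng: np.random.Generator,
    z_init: np.ndarray | None = None,
) -> dict:
    """One K=2 Gibbs chain; returns post-burn-in samples.

    Alternates (ii) sampling each genome's genotype at each site given
    the cells currently assigned to it, and (i) sampling each cell's
    genome given the genotype vectors.  Conditional assignment
    probabilities are stored alongside the sampled states for the
    relabelling step, and the running complete-state log-likelihood is
    tracked as the chain's fit score.
    """
    n_save = params.n_iterations - params.n_burnin
    z = rng.integers(0, 2, size=n_cells) if z_init is None else z_init.copy()
    p_save = np.empty((n_save, n_cells))
    z_save = np.empty((n_save, n_cells), dtype=np.int8)
    g_save = np.empty((n_save, 2, n_sites), dtype=np.int8)
    scores = np.empty(n_save)
    entry_idx = np.arange(len(rows))

    for it in range(params.n_iterations):
        # (ii) genotype step: per genome per site, softmax over pooled logliks
        G = np.empty((2, n_sites), dtype=np.int64)
        for k in range(2):
            mask = z[rows] == k
            site_ll = np.zeros((n_sites, 3))
            for g in range(3):
                site_ll[:, g] = np.bincount(
                    cols[mask], weights=L[mask, g], minlength=n_sites
                )
            gumbel = rng.gumbel(size=(n_sites, 3))
            G[k] = np.argmax(site_ll + gumbel, axis=1)
        # (i) assignment step: per cell, loglik under each genome
        ll = np.zeros((n_cells, 2))
        for k in range(2):
            lk = L[entry_idx, G[k][cols]]
            ll[:, k] = np.bincount(rows, weights=lk, minlength=n_cells)
        p1 = 1.0 / (1.0 + np.exp(np.clip(ll[:, 0] - ll[:, 1], -700, 700)))
        z = (rng.random(n_cells) < p1).astype(np.int64)
        if it >= params.n_burnin:
            s = it - params.n_burnin
            p_save[s] = p1
            z_save[s] = z
            g_save[s] = G
            scores[s] = float(ll[np.arange(n_cells), z].sum())
    return {"p": p_save, "z": z_save, "G": g_save, "score": float(scores.mean())}


def relabel_chain(p_samples: np.ndarray, max_rounds: int = 100) -> tuple[np.ndarray, bool]:
    """Stephens' relabelling for a two-component chain.

    ``p_samples`` holds, for each stored iteration, the per-cell
    conditional probability of genome 1.  Iteratively chooses, for each
    iteration, the label permutation (identity or swap) minimising the
    KL divergence between that iteration's assignment probabilities and
    their running average, until the permutations stabilise.  Returns
    (swap flags per iteration, converged).
    """
    P = np.clip(p_samples, _P_CLIP, 1 - _P_CLIP)
    T = P.shape[0]
    swap = np.zeros(T, dtype=bool)
    for _ in range(max_rounds):
        Pp = np.where(swap[:, None], 1.0 - P, P)
        q1 = np.clip(Pp.mean(axis=0), _P_CLIP, 1 - _P_CLIP)
        lq1, lq0 = np.log(q1), np.log1p(-q1)
        # Entropy terms are permutation-invariant, so minimising KL
        # reduces to maximising the cross term.
        cross_id = P @ lq1 + (1.0 - P) @ lq0
        cross_sw = P @ lq0 + (1.0 - P) @ lq1
        new_swap = cross_sw > cross_id
        if np.array_equal(new_swap, swap):
            return swap, True
        swap = new_swap
    logger.warning("Stephens relabelling did not converge in %d rounds", max_rounds)
    return swap, False


def _apply_relabelling(chain: dict, swap: np.ndarray) -> dict:
    p = np.where(swap[:, None], 1.0 - chain["p"], chain["p"])
    z = np.where(swap[:, None], 1 - chain["z"], chain["z"])
    G = chain["G"].copy()
    G[swap] = G[swap][:, ::-1, :]
    out = dict(chain)  # label permutations leave the fit score unchanged
    out.update({"p": p, "z": z, "G": G})
    return out


#: Chains whose mean complete-state log-likelihood trails the best chain
#: by more than this many nats are treated as stuck in an inferior mode
#: (typically the symmetric, unseparated one) and excluded from pooling.
_CHAIN_SCORE_SLACK = 200.0


def _fit_k2(pair: AlleleCountPair, params: MixtureParams) -> GenotypeModel:
    rows, cols, ref, alt = _sparse_union_entries(pair)
    L = _entry_logliks(ref, alt, params.error_rate)
    n_cells, n_sites = pair.shape
    z_init = None
    if params.init == "misfit":
        z_init = _misfit_seed(
            rows, cols, L, n_cells, n_sites, params.misfit_seed_fraction
        )
    elif params.init != "random":
        raise ValueError(f"unknown init {params.init!r}")
    root = np.random.SeedSequence(params.seed)
    chains = []
    for child in root.spawn(max(params.n_chains, 1)):
        rng = np.random.default_rng(child)
        chain = _gibbs_chain(rows, cols, L, n_cells, n_sites, params, rng, z_init)
        swap, converged = relabel_chain(chain["p"])
        chain = _apply_relabelling(chain, swap)
        chain["relabel_converged"] = converged
        chains.append(chain)

    # Keep only chains that reached the best mode, then align them to
    # the first kept chain by the global permutation minimising the
    # distance between mean assignment probabilities, and pool samples.
    best = max(c["score"] for c in chains)
    kept = [c for c in chains if c["score"] >= best - _CHAIN_SCORE_SLACK]
    ref_mean = kept[0]["p"].mean(axis=0)
    for chain in kept[1:]:
        m = chain["p"].mean(axis=0)
        if np.abs(m - ref_mean).sum() > np.abs((1.0 - m) - ref_mean).sum():
            flip = np.ones(chain["p"].shape[0], dtype=bool)
            relabelled = _apply_relabelling(chain, flip)
            chain.update(relabelled)

    z_all = np.concatenate([c["z"] for c in kept], axis=0)
    g_all = np.concatenate([c["G"] for c in kept], axis=0)

    freq1 = z_all.mean(axis=0)
    cell_post = np.column_stack([1.0 - freq1, freq1])
    geno_post = np.empty((2, n_sites, 3))
    for k in range(2):
        for g in range(3):
            geno_post[k, :, g] = (g_all[:, k, :] == g).mean(axis=0)
    return GenotypeModel(
        K=2,
        cells=list(pair.cells),
        site_keys=list(pair.sites),
        genotype_posterior=geno_post,
        cell_posterior=cell_post,
        diagnostics={
            "n_chains": len(chains),
            "n_chains_pooled": len(kept),
            "chain_scores": [c["score"] for c in chains],
            "relabel_converged": [c["relabel_converged"] for c in chains],
            "n_saved_samples": int(z_all.shape[0]),
        },
    )


def fit_mixture(pair: AlleleCountPair, params: MixtureParams, K: int = 2) -> GenotypeModel:
    """Fit the K-genome binomial mixture to per-cell allele counts.

    K=1 is computed in closed form (sites decouple); K=2 runs the Gibbs
    sampler with Stephens relabelling.  Seed-reproducible via
    ``params.seed``.
    """
    if K not in (1, 2):
        raise ValueError("K must be 1 or 2")
    if K == 1:
        return _fit_k1(pair, params)
    return _fit_k2(pair, params)


@dataclass
class ModelSelection:
    """Outcome of the K=1 vs K=2 decision."""

    chosen_k: int
    fraction_confident: float
    model: GenotypeModel

    @property
    def detected(self) -> bool:
        return self.chosen_k == 2


def select_model(
    model_k1: GenotypeModel, model_k2: GenotypeModel, params: MixtureParams
) -> ModelSelection:
    """Choose K=2 iff >= 90% of cells have assignment posterior > 75%.

    Selecting K=1 indicates the mixture fraction is below the level of
    detection: an unseparated K=2 fit reports posteriors near 0.5.
    """
    confident = model_k2.map_posterior > params.posterior_threshold
    frac = float(confident.mean())
    if frac >= params.cell_fraction_threshold:
        return ModelSelection(chosen_k=2, fraction_confident=frac, model=model_k2)
    return ModelSelection(chosen_k=1, fraction_confident=frac, model=model_k1)


def genotype_overlap(
    genotypes_a: Mapping[tuple, int],
    genotypes_b: Mapping[tuple, int],
    method: str = "map",
) -> float:
    """Agreement between two genotype sets over their shared SNV sites.

    ``method="map"`` (default) returns the percentage of shared sites
    with identical MAP genotypes.  ``method="dosage"`` instead returns
    100 x the Pearson correlation of alt-allele dosages (0/1/2) across
    shared sites, an alternative reading of comparing the "average
    genotype".
    """
    shared = sorted(set(genotypes_a) & set(genotypes_b))
    if not shared:
        raise ValueError("no shared SNV sites")
    if method == "map":
        agree = sum(genotypes_a[k] == genotypes_b[k] for k in shared)
        return 100.0 * agree / len(shared)
    if method == "dosage":
        a = np.array([genotypes_a[k] for k in shared], dtype=float)
        b = np.array([genotypes_b[k] for k in shared], dtype=float)
        if a.std() == 0 or b.std() == 0:
            raise ValueError("dosage correlation undefined for constant genotypes")
        return 100.0 * float(np.corrcoef(a, b)[0, 1])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class DemuxEvaluation:
    detected: bool
    sensitivity: float | None
    ppv: float | None
    called_minor_fraction: float | None


def evaluate_demux(
    truth_labels: Sequence[int], selection: ModelSelection | GenotypeModel
) -> DemuxEvaluation:
    """Score minor-population recovery against simulation truth.

    The minor population is the smaller predicted genome; sensitivity
    and PPV are computed for membership in it against the smaller truth
    group.  A K=1 call reports the population as not detected.
    """
    model = selection.model if isinstance(selection, ModelSelection) else selection
    if model.K == 1:
        return DemuxEvaluation(False, None, None, None)
    truth = np.asarray(truth_labels)
    truth_groups, truth_counts = np.unique(truth, return_counts=True)
    truth_minor = truth_groups[np.argmin(truth_counts)]
    pred = model.map_genome
    # Genome labels are arbitrary: align them to the truth groups by
    # overall agreement (resolves the degenerate 50:50 case), then score
    # membership in the genome aligned with the smaller truth group.
    agree_id = np.sum(pred == (truth == truth_groups[-1]).astype(int))
    agree_sw = len(truth) - agree_id
    aligned = pred if agree_id >= agree_sw else 1 - pred
    pred_minor = int(truth_minor == truth_groups[-1]) if len(truth_groups) > 1 else 0
    tp = int(np.sum((aligned == pred_minor) & (truth == truth_minor)))
    fn = int(np.sum((aligned != pred_minor) & (truth == truth_minor)))
    fp = int(np.sum((aligned == pred_minor) & (truth != truth_minor)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    return DemuxEvaluation(True, sens, ppv, model.minor_fraction)


def select_discriminating_snvs(
    umi_counts: sp.spmatrix,
    site_quals: Sequence[float],
    group_a_cells: Sequence[int],
    group_b_cells: Sequence[int],
    min_qual: float = 100.0,
    min_umi: int = 10,
    min_cells: int = 2,
) -> tuple[list[int], list[int]]:
    """Pick high-quality SNVs observed exclusively in one cell group.

    ``umi_counts`` is cells x sites UMI support.  A site passes when
    its call quality is >= ``min_qual``, it has >= ``min_umi`` total
    UMIs from >= ``min_cells`` cells, and it is observed in exactly one
    of the two (disjoint) groups.  Returns site indices (A-only,
    B-only).
    """
    if set(group_a_cells) & set(group_b_cells):
        raise ValueError("cell groups must be disjoint")
    counts = sp.csr_matrix(umi_counts)
    quals = np.asarray(site_quals, dtype=float)
    a = counts[list(group_a_cells)]
    b = counts[list(group_b_cells)]
    seen_a = np.asarray((a > 0).sum(axis=0)).ravel() > 0
    seen_b = np.asarray((b > 0).sum(axis=0)).ravel() > 0
    total_umi = np.asarray(counts.sum(axis=0)).ravel()
    n_cells = np.asarray((counts > 0).sum(axis=0)).ravel()
    ok = (quals >= min_qual) & (total_umi >= min_umi) & (n_cells >= min_cells)
    only_a = ok & seen_a & ~seen_b
    only_b = ok & seen_b & ~seen_a
    return list(np.flatnonzero(only_a)), list(np.flatnonzero(only_b))


@dataclass
class SnvLabelResult:
    labels: list[str]                  # per cell: "A", "B", "multiplet", "unassigned"
    fractions: np.ndarray              # per cell B/(A+B), nan when unassigned
    observed_multiplet_fraction: float
    inferred_multiplet_rate: float


def snv_label_cells(
    a_counts: Sequence[int],
    b_counts: Sequence[int],
    low: float = 0.2,
    high: float = 0.8,
) -> SnvLabelResult:
    """Label cells from enriched-SNV counts of two groups.

    For each cell, f = B/(A+B) over its group-enriched SNV
    observations: f < ``low`` labels the cell A, f > ``high`` labels it
    B, anything in between is a multiplet.  Cells with no informative
    observations are unassigned and excluded from the rate denominator.
    The inferred multiplet rate is twice the observed multiplet
    fraction (same-group multiplets are invisible).
    """
    a = np.asarray(a_counts, dtype=float)
    b = np.asarray(b_counts, dtype=float)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, b / total, np.nan)
    labels = []
    for f in frac:
        if np.isnan(f):
            labels.append("unassigned")
        elif f < low:
            labels.append("A")
        elif f > high:
            labels.append("B")
        else:
            labels.append("multiplet")
    n_assigned = int((total > 0).sum())
    n_multi = labels.count("multiplet")
    obs = n_multi / n_assigned if n_assigned else 0.0
    return SnvLabelResult(
        labels=labels,
        fractions=frac,
        observed_multiplet_fraction=obs,
        inferred_multiplet_rate=min(2.0 * obs, 1.0),
    )
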