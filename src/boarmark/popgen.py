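"""Population layer: haplotype classes, Fst, network, admixture, Evanno ΔK.

The extension-locus diplotypes define four haplotype classes (H1 = e,
H2 = E+, H3 = ED-class, H4 = EP3).  Chromosome counts per class per
population feed a Weir–Cockerham variance-components Fst (each
chromosome one haploid observation at a single multiallelic locus), a
pairwise-difference haplotype network, and a lightweight STRUCTURE-style
admixture model whose number of clusters is selected with the Evanno ΔK
statistic.

The admixture model is the standard no-linkage admixture model:
individual i has membership vector q_i ~ Dirichlet(alpha, ..., alpha),
cluster k has per-locus allele frequencies p_kl ~ Dirichlet(lambda), and
each allele copy is drawn by first picking a cluster from q_i, then an
allele from that cluster's frequencies.  Inference is by Gibbs sampling
(with alpha itself updated by Metropolis–Hastings, as the reference
implementation of this model family does) or by EM on the same
likelihood.  The correlated-allele-frequencies prior of the reference
implementation is not modelled; priors are independent Dirichlets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import lgamma

import networkx as nx
import numpy as np
import pandas as pd

from .classify import ALLELE_CLASS_PATTERNS, normalize_pair

#: Haplotype-class labels in their conventional H1..H4 order.
HAPLOTYPE_CLASSES = ("e", "E+", "ED", "EP3")
H_NAMES = {"e": "H1", "E+": "H2", "ED": "H3", "EP3": "H4"}

#: Default breed -> population pooling: the five breeds are one domestic
#: population; hybrids are excluded from the two-population comparison.
DEFAULT_POPULATION_MAP = {
    "WB": "wild_boar",
    "D": "domestic", "ZW": "domestic", "P": "domestic",
    "PL": "domestic", "PLW": "domestic",
}


class MonomorphicLocusError(ValueError):
    """Fst is undefined when both populations share one fixed allele."""


@dataclass
class HaplotypeTable:
    """Chromosome counts per haplotype class per population."""

    classes: tuple[str, ...]
    counts: dict[str, dict[str, int]]

    def n_chromosomes(self, pop: str) -> int:
        return sum(self.counts[pop].values())

    def frequencies(self, pop: str) -> np.ndarray:
        n = self.n_chromosomes(pop)
        return np.array([self.counts[pop].get(c, 0) / n for c in self.classes])

    def observed_classes(self) -> tuple[str, ...]:
        return tuple(c for c in self.classes
                     if any(p.get(c, 0) for p in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts).fillna(0).astype(int)
        df = df.reindex(list(self.classes))
        df.index = [f"{H_NAMES.get(c, '?')} ({c})" for c in df.index]
        df.index.name = "haplotype"
        return df


def build_haplotype_table(diplotypes, population_map=None) -> HaplotypeTable:
    """Tally chromosomes per haplotype class from resolved diplotypes.

    ``diplotypes`` is an iterable of objects with ``breed_label`` and
    ``pair`` attributes (e.g. :class:`~boarmark.classify.Diplotype`).
    Samples whose breed is absent from the population map are excluded;
    samples with an unrecognized pair raise.
    """
    pmap = DEFAULT_POPULATION_MAP if population_map is None else population_map
    counts: dict[str, dict[str, int]] = {}
    for d in diplotypes:
        pop = pmap.get(d.breed_label)
        if pop is None:
            continue
        for cls in d.pair:
            if cls not in HAPLOTYPE_CLASSES:
                raise ValueError(
                    f"sample {d.sample_id!r}: class {cls!r} has no haplotype "
                    "class; resolve or exclude it first")
            counts.setdefault(pop, {}).setdefault(cls, 0)
            counts[pop][cls] += 1
    return HaplotypeTable(classes=HAPLOTYPE_CLASSES, counts=counts)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FstResult:
    theta: float
    among: float                 # summed among-population variance component
    within: float                # summed within-population component
    populations: tuple[str, str]
    estimator: str = "weir-cockerham"


def fst_weir_cockerham(table: HaplotypeTable, pop_a: str, pop_b: str,
                       estimator: str = "weir-cockerham") -> FstResult:
    """Two-population Fst on haploid-coded chromosomes.

    The haplotype system is one multiallelic locus; every chromosome is
    one observation.  ``estimator="weir-cockerham"`` (default) is the
    variance-components theta, with per-allele among/within components
    summed over alleles; ``estimator="nei-gst"`` is the sample-weighted
    Nei Gst offered for comparison.  Raises
    :class:`MonomorphicLocusError` when no allele segregates in either
    population (theta is undefined, not zero).
    """
    for p in (pop_a, pop_b):
        if table.n_chromosomes(p) == 0:
            raise ValueError(f"population {p!r} is empty")
    n1 = table.n_chromosomes(pop_a)
    n2 = table.n_chromosomes(pop_b)
    p1 = table.frequencies(pop_a)
    p2 = table.frequencies(pop_b)
    if np.array_equal(p1 == 1.0, p2 == 1.0) and (p1 == 1.0).any():
        raise MonomorphicLocusError(
            f"{pop_a} and {pop_b} are fixed for the same haplotype; "
            "theta is undefined")

    n_t = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n_t

    if estimator == "nei-gst":
        hs = (n1 * (1 - (p1 ** 2).sum()) + n2 * (1 - (p2 ** 2).sum())) / n_t
        ht = 1 - (pbar ** 2).sum()
        return FstResult(theta=float((ht - hs) / ht), among=float(ht - hs),
                         within=float(hs), populations=(pop_a, pop_b),
                         estimator=estimator)
    if estimator != "weir-cockerham":
        raise ValueError(f"unknown estimator {estimator!r}")

    r = 2
    nc = (n_t - (n1 ** 2 + n2 ** 2) / n_t) / (r - 1)
    # Per-allele mean squares: among populations (MSP) and within (MSG),
    # each chromosome scored 0/1 for the allele.
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_t - r)
    a = (msp - msg) / nc          # among-population variance component
    b = msg                       # within-population component
    theta = float(a.sum() / (a.sum() + b.sum()))
    return FstResult(theta=theta, among=float(a.sum()), within=float(b.sum()),
                     populations=(pop_a, pop_b))


# ---------------------------------------------------------------------------
# Haplotype network
# ---------------------------------------------------------------------------

def class_distance(a: str, b: str) -> tuple[int, bool]:
    """Hamming distance over the discriminating SNP patterns.

    EP3 carries no distinguishing pattern at the panel loci; its distances
    default to the ED-class pattern and are flagged undefined.
    Returns ``(distance, defined)``.
    """
    defined = "EP3" not in (a, b)
    pa = ALLELE_CLASS_PATTERNS.get("ED" if a == "EP3" else a)
    pb = ALLELE_CLASS_PATTERNS.get("ED" if b == "EP3" else b)
    if pa is None or pb is None:
        raise ValueError(f"no SNP pattern for {a!r} or {b!r}")
    return sum(x != y for x, y in zip(pa, pb)), defined


def haplotype_network(weights: dict[str, int]) -> nx.Graph:
    """Complete pairwise-difference graph over the haplotype classes.

    Nodes carry chromosome-count ``weight`` and H-label attributes; edges
    carry the Hamming ``distance`` (and ``distance_defined=False`` where
    EP3's unresolvable pattern makes the distance a stand-in).  Edges of
    a minimum-spanning tree are marked ``mst=True`` for display.
    """
    g = nx.Graph()
    classes = [c for c in HAPLOTYPE_CLASSES if c in weights]
    for c in classes:
        g.add_node(c, weight=int(weights[c]), h_label=H_NAMES[c])
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            d, defined = class_distance(a, b)
            g.add_edge(a, b, distance=d, distance_defined=defined, mst=False)
    if g.number_of_edges():
        for u, v in nx.minimum_spanning_edges(g, weight="distance", data=False):
            g.edges[u, v]["mst"] = True
    return g


def network_to_frame(g: nx.Graph) -> pd.DataFrame:
    rows = [{"from": u, "to": v, "distance": d["distance"],
             "distance_defined": d["distance_defined"], "mst": d["mst"]}
            for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Admixture model
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    """One fitted replicate of the admixture model."""

    K: int
    Q: np.ndarray                # (n_samples, K), rows sum to 1
    P: np.ndarray                # (K, n_loci, max_alleles)
    log_likelihood: float        # posterior mean (Gibbs) or maximum (EM)
    log_likelihood_structure: float  # mean - var/2 deviance estimate
    seed: int
    method: str
    alpha: float
    ll_trace: np.ndarray = field(default=None, repr=False)


@dataclass
class AdmixtureRuns:
    """Replicate fits over a K range plus the settings that produced them."""

    k_range: tuple[int, ...]
    replicates: int
    fits: dict[int, list[AdmixtureFit]]
    seed: int
    burn_in: int
    n_reps: int

    def log_likelihoods(self) -> dict[int, list[float]]:
        return {k: [f.log_likelihood for f in fits]
                for k, fits in self.fits.items()}


def _validate_genotypes(genotypes) -> np.ndarray:
    x = np.asarray(genotypes, dtype=int)
    if x.ndim == 2:               # (n, 2): one locus
        x = x[:, None, :]
    if x.ndim != 3 or x.shape[2] != 2:
        raise ValueError("genotypes must have shape (n_samples, n_loci, 2)")
    if x.min() < 0:
        raise ValueError("allele codes must be non-negative integers")
    return x


def _ln_dirichlet_sym(q: np.ndarray, a: float) -> float:
    k = q.shape[1]
    return (q.shape[0] * (lgamma(k * a) - k * lgamma(a))
            + (a - 1.0) * np.log(np.clip(q, 1e-300, None)).sum())


def admixture_fit(genotypes, K: int, seed: int, *, method: str = "gibbs",
                  burn_in: int = 2_000, n_reps: int = 5_000,
                  alpha: float = 1.0, infer_alpha: bool = True,
                  lam: float = 1.0, max_iter: int = 500,
                  tol: float = 1e-8) -> AdmixtureFit:
    """Fit the admixture model for one K.

    ``genotypes`` is an integer array of shape ``(n_samples, n_loci, 2)``
    of per-locus allele codes (a single multiallelic locus and a
    per-SNP-site coding are both valid).  The Gibbs backend returns
    posterior means (deterministic given ``seed``); the EM backend
    maximises the same likelihood with a monotone trace.  ``K`` larger
    than the number of distinct multilocus genotypes triggers a warning
    but still runs.
    """
    x = _validate_genotypes(genotypes)
    if K < 1:
        raise ValueError("K must be >= 1")
    n, n_loci, _ = x.shape
    distinct = len({tuple(row.reshape(-1)) for row in x})
    if K > distinct:
        warnings.warn(f"K={K} exceeds the {distinct} distinct multilocus "
                      "genotypes; clusters will be redundant")
    n_alleles = np.array([x[:, l, :].max() + 1 for l in range(n_loci)])
    j_max = int(n_alleles.max())
    mask = np.zeros((n_loci, j_max), dtype=bool)   # valid allele slots
    for l in range(n_loci):
        mask[l, :n_alleles[l]] = True

    copies = x.reshape(n, -1)                       # (n, n_loci*2)
    ind = np.repeat(np.arange(n), n_loci * 2)
    loc = np.tile(np.repeat(np.arange(n_loci), 2), n)
    al = copies.reshape(-1)
    rng = np.random.default_rng(seed)

    if method == "em":
        return _fit_em(x, K, rng, seed, mask, ind, loc, al, n, n_loci,
                       j_max, max_iter, tol)
    if method != "gibbs":
        raise ValueError(f"unknown method {method!r}")

    q = rng.dirichlet(np.ones(K), size=n)
    p = rng.gamma(np.ones((K, n_loci, j_max))) * mask
    p = p / p.sum(-1, keepdims=True)

    a_cur = float(alpha)
    lls = np.empty(n_reps)
    q_accum = np.zeros_like(q)
    p_accum = np.zeros_like(p)
    alphas = np.empty(n_reps)
    n_copies = len(al)
    for t in range(burn_in + n_reps):
        w = q[ind] * p[:, loc, al].T                # (n_copies, K)
        probs = w / w.sum(1, keepdims=True)
        u = rng.random((n_copies, 1))
        z = (probs.cumsum(1) < u).sum(1)
        zc = np.zeros((n, K))
        np.add.at(zc, (ind, z), 1.0)
        g = rng.gamma(a_cur + zc)
        q = g / g.sum(1, keepdims=True)
        ac = np.zeros((K, n_loci, j_max))
        np.add.at(ac, (z, loc, al), 1.0)
        g = rng.gamma(lam + ac) * mask
        p = g / g.sum(-1, keepdims=True)
        # Rao-Blackwellised posterior means (conditional expectations given
        # the assignments) -- lower-variance estimates than the raw draws
        q_cond = (a_cur + zc) / (a_cur * K + n_loci * 2)
        pc = (lam + ac) * mask
        p_cond = pc / pc.sum(-1, keepdims=True)
        if infer_alpha and K > 1:
            prop = a_cur + rng.normal(0.0, 0.05)
            if 0.0 < prop <= 10.0:
                d = _ln_dirichlet_sym(q, prop) - _ln_dirichlet_sym(q, a_cur)
                if np.log(rng.random()) < d:
                    a_cur = prop
        if t >= burn_in:
            i = t - burn_in
            lls[i] = np.log((q[ind] * p[:, loc, al].T).sum(1)).sum()
            alphas[i] = a_cur
            q_accum += q_cond
            p_accum += p_cond
    q_mean = q_accum / n_reps
    p_mean = p_accum / n_reps
    ll_mean = float(lls.mean())
    return AdmixtureFit(
        K=K, Q=q_mean, P=p_mean, log_likelihood=ll_mean,
        log_likelihood_structure=float(ll_mean - lls.var() / 2.0),
        seed=seed, method="gibbs", alpha=float(alphas.mean()), ll_trace=lls,
    )


def _fit_em(x, K, rng, seed, mask, ind, loc, al, n, n_loci, j_max,
            max_iter, tol) -> AdmixtureFit:
    q = rng.dirichlet(np.ones(K), size=n)
    p = rng.gamma(np.ones((K, n_loci, j_max))) * mask
    p = p / p.sum(-1, keepdims=True)
    trace = []
    n_copies = len(al)
    for _ in range(max_iter):
        w = q[ind] * p[:, loc, al].T                # (n_copies, K)
        tot = w.sum(1, keepdims=True)
        trace.append(float(np.log(tot).sum()))
        resp = w / tot
        qc = np.zeros((n, K))
        np.add.at(qc, (ind,), resp)
        q = qc / (n_loci * 2)
        pc = np.zeros((K, n_loci, j_max))
        for k in range(K):
            np.add.at(pc[k], (loc, al), resp[:, k])
        denom = pc.sum(-1, keepdims=True)
        p = np.where(mask, np.divide(pc, denom, out=np.zeros_like(pc),
                                     where=denom > 0), 0.0)
        zero = (denom.squeeze(-1) == 0)
        if zero.any():              # empty cluster-locus: keep uniform
            for k, l in zip(*np.nonzero(zero)):
                p[k, l, mask[l]] = 1.0 / mask[l].sum()
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    ll = trace[-1]
    return AdmixtureFit(K=K, Q=q, P=p, log_likelihood=ll,
                        log_likelihood_structure=ll, seed=seed, method="em",
                        alpha=float("nan"), ll_trace=np.array(trace))


def run_admixture_scan(genotypes, k_range=range(1, 7), replicates: int = 10,
                       seed: int = 1, *, method: str = "gibbs",
                       burn_in: int = 2_000, n_reps: int = 5_000
                       ) -> AdmixtureRuns:
    """Replicate :func:`admixture_fit` over a K range.

    Replicate seeds are derived deterministically from ``seed`` so the
    whole scan is reproducible from one integer.
    """
    ks = tuple(k_range)
    ss = np.random.SeedSequence(seed)
    fits: dict[int, list[AdmixtureFit]] = {}
    children = iter(ss.spawn(len(ks) * replicates))
    for k in ks:
        fits[k] = []
        for _ in range(replicates):
            child_seed = int(next(children).generate_state(1)[0] % (2 ** 31))
            fits[k].append(admixture_fit(genotypes, k, child_seed,
                                         method=method, burn_in=burn_in,
                                         n_reps=n_reps))
    return AdmixtureRuns(k_range=ks, replicates=replicates, fits=fits,
                         seed=seed, burn_in=burn_in, n_reps=n_reps)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class EvannoResult:
    table: pd.DataFrame          # K, mean_L, sd_L, delta_K
    optimal_k: int | None


def evanno_delta_k(log_likelihoods: dict[int, list[float]]) -> EvannoResult:
    """Evanno ΔK = mean(|L(K+1) - 2 L(K) + L(K-1)|) / sd(L(K)).

    Requires at least three consecutive K values with at least two
    replicates each.  ΔK is defined only for interior K; a K whose
    replicate standard deviation is zero is excluded with a warning.  The
    optimum is the argmax of ΔK, or ``None`` when no interior K has a
    defined value (e.g. constant L across K).
    """
    ks = sorted(log_likelihoods)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(log_likelihoods[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    mean = {k: float(np.mean(log_likelihoods[k])) for k in ks}
    sd = {k: float(np.std(log_likelihoods[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            if sd[k] == 0.0:
                warnings.warn(f"sd(L) = 0 at K={k}; excluded from delta-K")
            else:
                dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
        rows.append({"K": k, "mean_L": mean[k], "sd_L": sd[k], "delta_K": dk})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["delta_K"])
    if valid.empty:
        warnings.warn("no interior K has a defined delta-K; no optimum")
        return EvannoResult(table=table, optimal_k=None)
    best = int(valid.loc[valid["delta_K"].idxmax(), "K"])
    return EvannoResult(table=table, optimal_k=best)


# ---------------------------------------------------------------------------
# Genotype codings for the admixture model
# ---------------------------------------------------------------------------

#: Allele codes for the haplotype-as-one-locus coding.
CLASS_CODES = {c: i for i, c in enumerate(HAPLOTYPE_CLASSES)}

#: 0/1 site codes (derived allele indicators at c.370, c.491, c.727).
_SITE_PATTERNS = {
    "E+": (0, 0, 0),
    "e": (0, 1, 1),
    "ED": (1, 0, 0),
    "EP3": (1, 0, 0),   # unresolvable at the panel sites
}


def diplotypes_to_locus_coding(diplotypes) -> np.ndarray:
    """(n, 1, 2) array: the haplotype class itself as one multiallelic locus."""
    out = [[[CLASS_CODES[a], CLASS_CODES[b]] for a, b in [normalize_pair(d.pair)]][0]
           for d in diplotypes]
    return np.array(out, dtype=int)[:, None, :]


def diplotypes_to_site_coding(diplotypes) -> np.ndarray:
    """(n, 3, 2) array: one biallelic locus per discriminating SNP site.

    This mirrors an aligned-sequence input where every segregating site
    is a locus; it is the default coding of the pipeline because the SNP
    sites, not the composite haplotype, are what a sequence-based cluster
    analysis actually sees.
    """
    n = 0
    rows = []
    for d in diplotypes:
        a, b = normalize_pair(d.pair)
        pa, pb = _SITE_PATTERNS[a], _SITE_PATTERNS[b]
        rows.append([[pa[l], pb[l]] for l in range(3)])
        n += 1
    return np.array(rows, dtype=int)
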