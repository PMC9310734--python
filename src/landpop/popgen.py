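"""Genotype-likelihood population-genetic estimators.

All estimators work directly on the three genotype likelihoods per
individual and site, without calling genotypes: the site frequency
spectrum (SFS) and its two-population joint analogue are estimated by
expectation-maximization over per-site allele-frequency likelihood
vectors; nucleotide diversity, heterozygosity, inbreeding coefficients,
pairwise genetic distances, a genotype-posterior covariance PCA and the
Hudson FST estimator are derived from those quantities.

The allele-frequency likelihood at a site with N diploids is

    L(d) ∝ sum over genotype configurations (g_1..g_N), sum g_i = d, of
           prod_i GL_i(g_i) * C(2, g_i) / C(2N, d)

computed by dynamic-programming convolution over individuals. The
hypergeometric normalization makes L exact (an indicator) for fully
certain genotypes and exactly flat for an all-missing site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .gl import GenotypeLikelihoodSet
from .matrices import DistanceMatrix
from .synthetic import LocalityTable

__all__ = [
    "SiteFrequencySpectrum",
    "DiversityEstimate",
    "InbreedingResult",
    "FstResult",
    "site_af_likelihood",
    "estimate_sfs",
    "fold_sfs",
    "intersect_sites",
    "theta_pi",
    "individual_heterozygosity",
    "estimate_inbreeding",
    "pairwise_genetic_distance",
    "gl_covariance_pca",
    "joint_sfs",
    "fst_from_joint_sfs",
    "fst_matrix",
]

_EM_LL_TOL = 1e-9   # EM log-likelihood may never decrease beyond this


# ---------------------------------------------------------------------------
# results


@dataclass
class SiteFrequencySpectrum:
    counts: np.ndarray          # expected site counts per allele-count class
    n_haplotypes: int           # 2N
    polarization: str = "unfolded"
    converged: bool = True
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expect = self.n_haplotypes + 1 if self.polarization == "unfolded" \
            else self.n_haplotypes // 2 + 1
        if self.counts.size != expect:
            raise ValueError(
                f"{self.polarization} SFS for {self.n_haplotypes} haplotypes "
                f"needs {expect} classes, got {self.counts.size}"
            )

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(repr(float(c)) for c in self.counts) + "\n")


@dataclass
class DiversityEstimate:
    theta_pi_total: float
    theta_pi_per_site: float
    n_sites: float


@dataclass
class InbreedingResult:
    F_per_individual: np.ndarray
    minor_freq_per_site: np.ndarray
    loglik_trace: list
    iterations: int
    converged: bool


@dataclass
class JointSFS:
    counts: np.ndarray          # (2N1+1, 2N2+1) expected site counts
    n_haplotypes: tuple[int, int]
    converged: bool = True
    loglik_trace: list = field(default_factory=list)

    @property
    def n_sites(self) -> float:
        return float(self.counts.sum())


@dataclass
class FstResult:
    fst_weighted: float
    numerator_sum: float
    denominator_sum: float
    joint_sfs: JointSFS | None = None
    method: str = "hudson"
    defined: bool = True


# ---------------------------------------------------------------------------
# allele-frequency likelihoods and 1-D SFS


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def site_af_likelihood(gls: np.ndarray) -> np.ndarray:
    """Allele-frequency likelihood vectors L(d), d = 0..2N, for each site.

    gls: (n_sites, N, 3) or (N, 3) likelihoods. Returns (n_sites, 2N+1)
    (or (2N+1,)), normalized so each site's maximum is 1. An all-missing
    site comes back exactly flat (uninformative).
    """
    single = gls.ndim == 2
    if single:
        gls = gls[None]
    n_sites, n_ind, _ = gls.shape
    if n_ind < 1:
        raise ValueError("need at least one diploid individual")
    # DP convolution over individuals with genotype multiplicities C(2,g) = 1,2,1
    z = np.zeros((n_sites, 2 * n_ind + 1))
    z[:, 0] = 1.0
    width = 0
    for i in range(n_ind):
        nz = np.zeros_like(z)
        nz[:, : width + 1] += z[:, : width + 1] * gls[:, i, 0, None]
        nz[:, 1 : width + 2] += z[:, : width + 1] * (2.0 * gls[:, i, 1, None])
        nz[:, 2 : width + 3] += z[:, : width + 1] * gls[:, i, 2, None]
        z = nz
        width += 2
        # rescale to avoid underflow on long convolutions
        mx = z.max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        z /= mx
    d = np.arange(2 * n_ind + 1)
    z /= np.exp(_log_binom(2 * n_ind, d))[None, :]
    mx = z.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    z /= mx
    return z[0] if single else z


def _sfs_em(
    like: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, list, bool]:
    """EM for class proportions given per-site class likelihoods (S, K)."""
    n_sites, k = like.shape
    phi = np.full(k, 1.0 / k)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        weighted = like * phi[None, :]
        z = weighted.sum(axis=1)
        if np.any(z == 0):
            raise ValueError("site with zero likelihood under every class")
        trace.append(float(np.log(z).sum()))
        if len(trace) > 1 and trace[-1] < trace[-2] - _EM_LL_TOL:
            raise RuntimeError("EM log-likelihood decreased — estimator bug")
        post = weighted / z[:, None]
        phi_new = post.mean(axis=0)
        delta = np.abs(phi_new - phi).max()
        phi = phi_new
        if delta < tol:
            converged = True
            break
    return phi * n_sites, trace, converged


def estimate_sfs(
    gl: GenotypeLikelihoodSet,
    fold: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> SiteFrequencySpectrum:
    """Maximum-likelihood SFS by EM over per-site allele-frequency likelihoods."""
    like = site_af_likelihood(gl.likelihoods)
    if not np.any(like.max(axis=1) > like.min(axis=1)):
        raise ValueError("no informative site (all allele-frequency likelihoods flat)")
    counts, trace, converged = _sfs_em(like, tol, max_iter)
    if not converged:
        warnings.warn("SFS EM did not converge within max_iter", RuntimeWarning)
    sfs = SiteFrequencySpectrum(
        counts, 2 * gl.n_individuals, "unfolded", converged, trace
    )
    return fold_sfs(sfs) if fold else sfs


def fold_sfs(sfs: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Collapse derived-count classes d and 2N-d into minor-allele classes."""
    if sfs.polarization == "folded":
        return sfs
    n = sfs.n_haplotypes
    half = n // 2
    folded = np.zeros(half + 1)
    for d in range(n + 1):
        folded[min(d, n - d)] += sfs.counts[d]
    return SiteFrequencySpectrum(folded, n, "folded", sfs.converged, list(sfs.loglik_trace))


def intersect_sites(site_lists: list[list[str]]) -> list[str]:
    """Sorted intersection of per-locality site-ID lists."""
    if len(site_lists) < 2:
        raise ValueError("need at least two site lists to intersect")
    shared = set(site_lists[0])
    for lst in site_lists[1:]:
        shared &= set(lst)
    if not shared:
        raise ValueError("site lists have an empty intersection")
    return sorted(shared)


def theta_pi(sfs: SiteFrequencySpectrum) -> DiversityEstimate:
    """Nucleotide diversity: average pairwise differences from the SFS.

    theta_pi_total = sum_i i(n-i) eta_i / C(n,2) with n the haplotype count;
    the same weights apply to folded classes since i(n-i) = (n-i)i.
    """
    n = sfs.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    idx = np.arange(sfs.counts.size)
    weights = idx * (n - idx)
    total = float((weights * sfs.counts).sum() / (n * (n - 1) / 2))
    n_sites = sfs.n_sites
    return DiversityEstimate(total, total / n_sites if n_sites > 0 else np.nan, n_sites)


def individual_heterozygosity(
    gls: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> float:
    """Heterozygous fraction for one diploid: class-1 mass of a 3-class SFS EM.

    gls: (n_sites, 3) likelihoods. Returns NaN (with a warning) if every
    site is missing.
    """
    gls = np.asarray(gls, dtype=float)
    informative = gls.max(axis=1) > gls.min(axis=1)
    if not informative.any():
        warnings.warn("individual has no informative site; heterozygosity undefined",
                      RuntimeWarning)
        return float("nan")
    counts, _, _ = _sfs_em(gls, tol, max_iter)
    return float(counts[1] / counts.sum())


# ---------------------------------------------------------------------------
# inbreeding


def estimate_inbreeding(
    gl: GenotypeLikelihoodSet,
    max_iter_stage2: int = 1500,
    stage1_iter: int = 100,
    tol: float = 1e-8,
    f_init: float = 0.01,
) -> InbreedingResult:
    """Per-individual inbreeding coefficients by two-stage EM.

    Model: with probability f_i the genotype is autozygous (a single allele
    drawn at frequency p_s and doubled), otherwise Hardy–Weinberg, giving
    the genotype prior (q^2 + f p q, 2 p q (1 - f), p^2 + f p q). Stage 1
    runs a short EM from near-neutral starting values; stage 2 restarts
    from those values with the deep iteration cap.
    """
    if gl.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    gls = gl.likelihoods
    L0, L1, L2 = gls[..., 0], gls[..., 1], gls[..., 2]
    n_sites, n_ind = L0.shape

    # initial frequencies: mean posterior dosage under a flat genotype prior
    tot = L0 + L1 + L2
    p = np.clip(((L1 + 2 * L2) / tot).mean(axis=1) / 2.0, 1e-4, 1 - 1e-4)
    f = np.full(n_ind, f_init)
    trace: list[float] = []

    def em_pass(f, p, iters, pass_tol):
        converged = False
        used = 0
        for it in range(iters):
            used = it + 1
            q = 1 - p
            pc, qc = p[:, None], q[:, None]
            a0 = f[None, :] * qc * L0                 # autozygous, genotype 0
            a2 = f[None, :] * pc * L2                 # autozygous, genotype 2
            b0 = (1 - f[None, :]) * qc**2 * L0
            b1 = (1 - f[None, :]) * 2 * pc * qc * L1
            b2 = (1 - f[None, :]) * pc**2 * L2
            z = a0 + a2 + b0 + b1 + b2
            trace.append(float(np.log(z).sum()))
            if len(trace) > 1 and trace[-1] < trace[-2] - _EM_LL_TOL * max(1, abs(trace[-2])):
                raise RuntimeError("inbreeding EM log-likelihood decreased")
            f_new = ((a0 + a2) / z).mean(axis=0)
            # allele-count M-step: autozygous genotypes carry one independent allele
            num = ((b1 + 2 * b2 + a2) / z).sum(axis=1)
            den = ((2 * (b0 + b1 + b2) + a0 + a2) / z).sum(axis=1)
            p_new = np.clip(num / den, 1e-6, 1 - 1e-6)
            delta = max(np.abs(f_new - f).max(), np.abs(p_new - p).max())
            f, p = np.clip(f_new, 0, 1), p_new
            if delta < pass_tol:
                converged = True
                break
        return f, p, converged, used

    f, p, _, _ = em_pass(f, p, stage1_iter, 1e-5)
    f, p, converged, used = em_pass(f, p, max_iter_stage2, tol)
    return InbreedingResult(f, p, trace, used, converged)


# ---------------------------------------------------------------------------
# distances and covariance


_DOSAGE_KERNEL = np.array([[0.0, 0.5, 1.0], [0.5, 0.0, 0.5], [1.0, 0.5, 0.0]])
_MISMATCH_KERNEL = 1.0 - np.eye(3)


def pairwise_genetic_distance(
    gl: GenotypeLikelihoodSet,
    site_freqs: np.ndarray | None = None,
    kernel: str = "dosage",
) -> DistanceMatrix:
    """Expected genotype-distance matrix between individuals.

    D(i, j) averages sum_{g,h} P_i(g) P_j(h) k(g, h) over sites covered in
    both individuals, with k = |g-h|/2 on dosages (default) or 0/1 mismatch.
    Genotype posteriors use a flat prior unless per-site allele frequencies
    are supplied (then a Hardy–Weinberg prior).
    """
    if gl.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    K = _DOSAGE_KERNEL if kernel == "dosage" else _MISMATCH_KERNEL
    gls = gl.likelihoods
    if site_freqs is not None:
        p = np.asarray(site_freqs)[:, None]
        prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)
        gls = gls * prior
    post = gls / gls.sum(axis=2, keepdims=True)
    covered = ~gl.missing_mask()
    n = gl.n_individuals
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = covered[:, i] & covered[:, j]
            if not both.any():
                out[i, j] = out[j, i] = np.nan
                continue
            d = np.einsum("sg,gh,sh->s", post[both, i], K, post[both, j])
            out[i, j] = out[j, i] = d.mean()
    return DistanceMatrix(list(gl.individuals), out, "genetic")


@dataclass
class PCAResult:
    covariance: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray      # (n_ind, n_ind) column k = scores on PC k
    n_sites_used: int


def _hwe_site_freqs(gls: np.ndarray, iters: int = 50, tol: float = 1e-6) -> np.ndarray:
    """Per-site allele frequency by EM under Hardy–Weinberg on the GLs."""
    n_sites = gls.shape[0]
    p = np.full(n_sites, 0.25)
    for _ in range(iters):
        pc = p[:, None]
        w = np.stack([(1 - pc) ** 2, 2 * pc * (1 - pc), pc**2], axis=-1) * gls
        w /= w.sum(axis=2, keepdims=True)
        p_new = np.clip((w[..., 1] + 2 * w[..., 2]).mean(axis=1) / 2, 1e-6, 1 - 1e-6)
        if np.abs(p_new - p).max() < tol:
            p = p_new
            break
        p = p_new
    return p


def gl_covariance_pca(
    gl: GenotypeLikelihoodSet,
    maf_bounds: tuple[float, float] = (0.01, 0.99),
    min_sites: int = 10,
) -> PCAResult:
    """Genotype-posterior covariance matrix and its eigendecomposition.

    Expected dosages come from Hardy–Weinberg genotype posteriors; the
    covariance standardizes each site by 2 p(1-p) and drops near-fixed
    sites outside the allele-frequency bounds.
    """
    if gl.n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    gls = gl.likelihoods
    p = _hwe_site_freqs(gls)
    keep = (p > maf_bounds[0]) & (p < maf_bounds[1])
    if keep.sum() < min_sites:
        raise ValueError(f"only {keep.sum()} sites retained; need >= {min_sites}")
    pc = p[keep][:, None]
    w = np.stack([(1 - pc) ** 2, 2 * pc * (1 - pc), pc**2], axis=-1) * gls[keep]
    w /= w.sum(axis=2, keepdims=True)
    dosage = w[..., 1] + 2 * w[..., 2]
    centered = (dosage - 2 * pc) / np.sqrt(2 * pc * (1 - pc))
    cov = centered.T @ centered / keep.sum()
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return PCAResult(cov, vals[order], vecs[:, order], int(keep.sum()))


# ---------------------------------------------------------------------------
# joint SFS and FST


def joint_sfs(
    glA: GenotypeLikelihoodSet,
    glB: GenotypeLikelihoodSet,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> JointSFS:
    """Two-population joint SFS by EM on shared sites.

    The E-step factorizes: with per-site class likelihoods A (S x K1) and
    B (S x K2) and prior Phi, the accumulated posterior is
    Phi * ((A / Z)^T B) with per-site normalizer Z = A Phi B^T diagonal.
    """
    shared = intersect_sites([list(glA.site_ids), list(glB.site_ids)])
    a = glA.subset_sites(shared)
    b = glB.subset_sites(shared)
    A = site_af_likelihood(a.likelihoods)
    B = site_af_likelihood(b.likelihoods)
    n_sites, k1 = A.shape
    k2 = B.shape[1]
    phi = np.full((k1, k2), 1.0 / (k1 * k2))
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        T = A @ phi                       # (S, K2)
        z = np.einsum("sk,sk->s", T, B)
        if np.any(z == 0):
            raise ValueError("site with zero likelihood under every joint class")
        trace.append(float(np.log(z).sum()))
        if len(trace) > 1 and trace[-1] < trace[-2] - _EM_LL_TOL * max(1, abs(trace[-2])):
            raise RuntimeError("joint-SFS EM log-likelihood decreased")
        phi_new = phi * ((A / z[:, None]).T @ B) / n_sites
        delta = np.abs(phi_new - phi).max()
        phi = phi_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("joint-SFS EM did not converge within max_iter", RuntimeWarning)
    return JointSFS(phi * n_sites, (k1 - 1, k2 - 1), converged, trace)


def fst_from_joint_sfs(sfs2d: JointSFS, method: str = "hudson") -> FstResult:
    """Weighted (ratio-of-sums) FST from a joint SFS.

    Hudson/Bhatia: per class (d1, d2) with sample frequencies p1, p2,
    numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    denominator p1(1-p2) + p2(1-p1), each weighted by class mass.
    """
    n1, n2 = sfs2d.n_haplotypes
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 haplotypes (1 diploid)")
    d1 = np.arange(n1 + 1)[:, None] / n1
    d2 = np.arange(n2 + 1)[None, :] / n2
    if method == "hudson":
        num = (d1 - d2) ** 2 - d1 * (1 - d1) / (n1 - 1) - d2 * (1 - d2) / (n2 - 1)
        den = d1 * (1 - d2) + d2 * (1 - d1)
    elif method == "reynolds":
        # Reynolds-style ANOVA estimator: per-class mean squares between and
        # within populations, combined as a ratio of sums
        pbar = (n1 * d1 + n2 * d2) / (n1 + n2)
        msp = n1 * (d1 - pbar) ** 2 + n2 * (d2 - pbar) ** 2
        msg = (n1 * d1 * (1 - d1) + n2 * d2 * (1 - d2)) / (n1 + n2 - 2)
        nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
        num = msp - msg
        den = msp + (nc - 1) * msg
    else:
        raise ValueError(f"unknown FST estimator '{method}'")
    # classes monomorphic in both populations carry no information
    mono = ((d1 == 0) | (d1 == 1)) & ((d2 == 0) | (d2 == 1)) & (d1 == d2)
    num = np.where(mono, 0.0, num)
    den = np.where(mono, 0.0, den)
    w = sfs2d.counts
    num_sum = float((w * num).sum())
    den_sum = float((w * den).sum())
    if den_sum <= 0:
        return FstResult(float("nan"), num_sum, den_sum, sfs2d, method, defined=False)
    return FstResult(num_sum / den_sum, num_sum, den_sum, sfs2d, method)


def fst_matrix(
    gl: GenotypeLikelihoodSet,
    localities: LocalityTable,
    method: str = "hudson",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[DistanceMatrix, np.ndarray]:
    """Pairwise locality FST matrix (negatives clamped to 0; raw values returned too)."""
    groups = []
    for name in localities.names:
        members = [
            m for m in localities.members(name)["individual"] if m in gl.individuals
        ]
        if len(members) < 2:
            warnings.warn(f"locality {name} has < 2 genotyped individuals; excluded")
            continue
        groups.append((name, members))
    if len(groups) < 2:
        raise ValueError("need at least 2 localities with >= 2 individuals")
    names = [g[0] for g in groups]
    k = len(groups)
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub_i = gl.subset_individuals(groups[i][1])
            sub_j = gl.subset_individuals(groups[j][1])
            res = fst_from_joint_sfs(joint_sfs(sub_i, sub_j, tol, max_iter), method)
            raw[i, j] = raw[j, i] = res.fst_weighted
    clamped = np.clip(raw, 0, None)
    np.fill_diagonal(clamped, 0.0)
    return DistanceMatrix(names, clamped, "FST"), raw
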