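"""Per-locus parentage likelihoods.

The core quantity is the per-locus likelihood ratio of a candidate
parent-offspring dyad against the unrelated hypothesis, under an
error model in which each observed genotype equals the true genotype
with probability 1 - eps and is otherwise an independent Hardy-Weinberg
draw.  Integrating that mistyping over both members gives the closed
form

    LR_obs = (1 - eps)^2 * LR_exact + (2*eps - eps^2)

because Hardy-Weinberg replacement leaves both the unrelated likelihood
and the marginals of the parent-offspring joint unchanged.  Triad
(dam-sire-offspring) likelihoods are obtained numerically by folding the
same error matrix over all three members of the exact joint.

Tables are precomputed per locus over the small space of unordered
genotypes, so scoring millions of dyads reduces to integer indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import Locus, PanelConfig, geno_code, n_geno_codes

__all__ = ["transmission_prob", "LikelihoodTables", "build_tables"]


def hw_probs(freqs: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg probabilities over canonical genotype codes."""
    k = len(freqs)
    out = np.zeros(n_geno_codes(k))
    for j in range(k):
        for i in range(j + 1):
            out[geno_code(i, j)] = freqs[i] ** 2 if i == j else 2 * freqs[i] * freqs[j]
    return out


def transmission_matrix(freqs: np.ndarray) -> np.ndarray:
    """T[o, p] = P(offspring genotype o | parent genotype p, HW random mate)."""
    k = len(freqs)
    G = n_geno_codes(k)
    T = np.zeros((G, G))
    for pj in range(k):
        for pi in range(pj + 1):
            p = geno_code(pi, pj)
            for transmitted, w in ((pi, 0.5), (pj, 0.5)):
                for mate in range(k):
                    T[geno_code(transmitted, mate), p] += w * freqs[mate]
    return T


def pair_offspring_matrix(freqs: np.ndarray) -> np.ndarray:
    """P3[o, p1, p2] = P(offspring o | parents p1 and p2)."""
    k = len(freqs)
    G = n_geno_codes(k)
    P3 = np.zeros((G, G, G))
    for aj in range(k):
        for ai in range(aj + 1):
            p1 = geno_code(ai, aj)
            for bj in range(k):
                for bi in range(bj + 1):
                    p2 = geno_code(bi, bj)
                    for x, wx in ((ai, 0.5), (aj, 0.5)):
                        for y, wy in ((bi, 0.5), (bj, 0.5)):
                            P3[geno_code(x, y), p1, p2] += wx * wy
    return P3


def share_matrix(k: int) -> np.ndarray:
    """share[a, b] True iff unordered genotypes a and b share >= 1 allele."""
    G = n_geno_codes(k)
    pairs = [(i, j) for j in range(k) for i in range(j + 1)]
    order = np.zeros((G, 2), dtype=int)
    for i, j in pairs:
        order[geno_code(i, j)] = (i, j)
    a = order[:, None, :]
    b = order[None, :, :]
    return (
        (a[..., 0] == b[..., 0])
        | (a[..., 0] == b[..., 1])
        | (a[..., 1] == b[..., 0])
        | (a[..., 1] == b[..., 1])
    )


def transmission_prob(
    offspring_geno: tuple[int, int], parent_geno: tuple[int, int], allele_freqs
) -> tuple[float, float]:
    """Single-locus dyad probabilities, no genotyping error.

    Returns ``(po_prob, unrelated_prob)``: the probability of the
    offspring genotype given the parent (with a Hardy-Weinberg random
    mate) and the unconditional Hardy-Weinberg probability of the
    offspring genotype.
    """
    freqs = np.asarray(allele_freqs, dtype=float)
    k = len(freqs)
    for a in (*offspring_geno, *parent_geno):
        if not 0 <= a < k:
            raise ValueError(f"allele index {a} absent from panel ({k} alleles)")
    T = transmission_matrix(freqs)
    hw = hw_probs(freqs)
    o = geno_code(*offspring_geno)
    p = geno_code(*parent_geno)
    return float(T[o, p]), float(hw[o])


@dataclass
class LikelihoodTables:
    """Precomputed per-locus scoring tables for one (panel, eps)."""

    panel: PanelConfig
    eps: float
    log_lr: list[np.ndarray]  # per locus (G, G): ln LR_obs[o, parent]
    share: list[np.ndarray]  # per locus (G, G) bool
    hw: list[np.ndarray]  # per locus (G,)
    _triad_log_lr: list | None = field(default=None, repr=False)
    _compat3: list | None = field(default=None, repr=False)

    # ---- triad tables, built on first use ------------------------------
    def triad_tables(self) -> tuple[list, list]:
        if self._triad_log_lr is None:
            tl, tc = [], []
            e = self.eps
            for locus, hw in zip(self.panel.loci, self.hw):
                freqs = locus.freqs
                P3 = pair_offspring_matrix(freqs)
                J3 = P3 * hw[None, :, None] * hw[None, None, :]
                G = len(hw)
                E = (1.0 - e) * np.eye(G) + e * hw[:, None]  # E[obs, true]
                L = np.einsum("ox,py,qz,xyz->opq", E, E, E, J3, optimize=True)
                denom = hw[:, None, None] * hw[None, :, None] * hw[None, None, :]
                with np.errstate(divide="ignore"):
                    tl.append(np.log(L / denom))
                tc.append(P3 > 0)
            self._triad_log_lr, self._compat3 = tl, tc
        return self._triad_log_lr, self._compat3

    # ---- vectorised dyad scoring ---------------------------------------
    def dyad_scores(
        self, codes_o: np.ndarray, codes_c: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Score all offspring x candidate dyads.

        ``codes_o`` is (n, L) and ``codes_c`` is (m, L) of canonical
        genotype codes with -1 for missing.  Returns ``(lod, n_mismatch,
        n_loci_used)`` each of shape (n, m); loci missing in either
        member are skipped.
        """
        n, L = codes_o.shape
        m = codes_c.shape[0]
        lod = np.zeros((n, m))
        nmis = np.zeros((n, m), dtype=np.int32)
        nloci = np.zeros((n, m), dtype=np.int32)
        for l in range(L):
            co = codes_o[:, l]
            cc = codes_c[:, l]
            valid = (co >= 0)[:, None] & (cc >= 0)[None, :]
            co_s = np.where(co >= 0, co, 0)
            cc_s = np.where(cc >= 0, cc, 0)
            contrib = self.log_lr[l][co_s[:, None], cc_s[None, :]]
            lod += np.where(valid, contrib, 0.0)
            nmis += (valid & ~self.share[l][co_s[:, None], cc_s[None, :]]).astype(np.int32)
            nloci += valid.astype(np.int32)
        return lod, nmis, nloci

    def triad_scores(
        self, codes_o: np.ndarray, codes_p1: np.ndarray, codes_p2: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Score matched rows of (P, L) code arrays as dam-sire-offspring triads.

        Returns ``(triad_lod, triad_mismatch)`` of shape (P,); loci
        missing in any member are skipped, and a triad mismatch is a
        locus where the offspring genotype cannot be produced by the
        parent pair.
        """
        tl, tc = self.triad_tables()
        P, L = codes_o.shape
        lod = np.zeros(P)
        nmis = np.zeros(P, dtype=np.int32)
        for l in range(L):
            o, a, b = codes_o[:, l], codes_p1[:, l], codes_p2[:, l]
            valid = (o >= 0) & (a >= 0) & (b >= 0)
            o_s, a_s, b_s = (np.where(v >= 0, v, 0) for v in (o, a, b))
            lod += np.where(valid, tl[l][o_s, a_s, b_s], 0.0)
            nmis += (valid & ~tc[l][o_s, a_s, b_s]).astype(np.int32)
        return lod, nmis


def build_tables(panel: PanelConfig, eps: float | None = None) -> LikelihoodTables:
    """Build dyad scoring tables for a panel at error rate ``eps``."""
    e = panel.error_rate if eps is None else eps
    if not 0.0 <= e < 1.0:
        raise ValueError(f"error rate {e} outside [0, 1)")
    log_lr, share, hw = [], [], []
    for locus in panel.loci:
        freqs = locus.freqs
        h = hw_probs(freqs)
        T = transmission_matrix(freqs)
        with np.errstate(divide="ignore", invalid="ignore"):
            lr_exact = T / h[:, None]
        lr_obs = (1.0 - e) ** 2 * lr_exact + (2.0 * e - e * e)
        with np.errstate(divide="ignore"):
            log_lr.append(np.log(lr_obs))
        share.append(share_matrix(locus.n_alleles))
        hw.append(h)
    return LikelihoodTables(panel=panel, eps=e, log_lr=log_lr, share=share, hw=hw)
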