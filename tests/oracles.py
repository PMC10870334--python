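"""Independent brute-force oracles for the statistics modules.

Everything here is written as plain per-locus scalar loops, straight from
the estimator definitions, deliberately sharing no code with the package
implementation.
"""

from __future__ import annotations

import math

MISSING = -1


def per_pop_locus(calls_col, codes, k):
    """(n, p, het) per population for one locus (lists of length k)."""
    n, p, het = [], [], []
    for g in range(k):
        vals = [c for c, z in zip(calls_col, codes) if z == g and c != MISSING]
        n.append(len(vals))
        if vals:
            p.append(sum(vals) / (2 * len(vals)))
            het.append(sum(1 for v in vals if v == 1) / len(vals))
        else:
            p.append(None)
            het.append(None)
    return n, p, het


def diversity_oracle(calls, codes, k):
    """Nei/Chesser per-locus components averaged across usable loci.

    Returns dict with HO, HS, HT, DST, FST, FIS, DEST (DEST None if k==1).
    """
    ho_list, hs_list, ht_list = [], [], []
    n_samples, n_loci = len(calls), len(calls[0])
    for l in range(n_loci):
        col = [calls[i][l] for i in range(n_samples)]
        n, p, het = per_pop_locus(col, codes, k)
        if any(x == 0 for x in n):
            continue
        ntilde = k / sum(1.0 / x for x in n)
        if ntilde <= 1:
            continue
        ho = sum(het) / k
        hom = sum(pp**2 + (1 - pp) ** 2 for pp in p) / k
        hs = ntilde / (ntilde - 1) * (1 - hom - ho / (2 * ntilde))
        pbar = sum(p) / k
        ht = 1 - (pbar**2 + (1 - pbar) ** 2) + hs / (ntilde * k) - ho / (2 * ntilde * k)
        ho_list.append(ho)
        hs_list.append(hs)
        ht_list.append(ht)
    ho = sum(ho_list) / len(ho_list)
    hs = sum(hs_list) / len(hs_list)
    ht = sum(ht_list) / len(ht_list)
    if k == 1:
        return {
            "HO": ho, "HS": hs, "HT": hs, "DST": 0.0, "FST": 0.0,
            "FIS": 1 - ho / hs if hs else float("nan"), "DEST": None,
        }
    dst = ht - hs
    return {
        "HO": ho,
        "HS": hs,
        "HT": ht,
        "DST": dst,
        "FST": dst / ht,
        "FIS": 1 - ho / hs,
        "DEST": (k / (k - 1)) * dst / (1 - hs),
    }


def wc_theta_oracle(calls, codes):
    """Weir & Cockerham (1984) theta for two populations, ratio of
    averages across loci (straight from the published a/b/c formulas)."""
    n_samples, n_loci = len(calls), len(calls[0])
    num = den = 0.0
    r = 2
    for l in range(n_loci):
        col = [calls[i][l] for i in range(n_samples)]
        n, p, het = per_pop_locus(col, codes, r)
        if any(x == 0 for x in n):
            continue
        nbar = sum(n) / r
        if nbar <= 1:
            continue
        nc = (sum(n) - sum(x**2 for x in n) / sum(n)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, het)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else float("nan")


def summaries_oracle(calls, codes, k):
    """Expected heterozygosity, monomorphic proportion, Nei D and f3 by
    scalar loops (FST covered by wc_theta_oracle)."""
    n_samples, n_loci = len(calls), len(calls[0])
    per_locus = []
    for l in range(n_loci):
        col = [calls[i][l] for i in range(n_samples)]
        per_locus.append(per_pop_locus(col, codes, k))
    out = {}
    for g in range(k):
        hx, mono, cnt = 0.0, 0, 0
        for n, p, _ in per_locus:
            if n[g] == 0:
                continue
            cnt += 1
            hx += 2 * p[g] * (1 - p[g]) * (2 * n[g]) / (2 * n[g] - 1)
            mono += p[g] in (0.0, 1.0)
        out[f"Hexp_{g}"] = hx / cnt
        out[f"mono_{g}"] = mono / cnt
    for a in range(k):
        for b in range(a + 1, k):
            ja = jb = jab = 0.0
            cnt = 0
            for n, p, _ in per_locus:
                if n[a] == 0 or n[b] == 0:
                    continue
                cnt += 1
                ja += p[a] ** 2 + (1 - p[a]) ** 2
                jb += p[b] ** 2 + (1 - p[b]) ** 2
                jab += p[a] * p[b] + (1 - p[a]) * (1 - p[b])
            ja, jb, jab = ja / cnt, jb / cnt, jab / cnt
            out[f"nei_{a}_{b}"] = -math.log(jab / math.sqrt(ja * jb))
    for t in range(k):
        others = [o for o in range(k) if o != t]
        for i, a in enumerate(others):
            for b in others[i + 1:]:
                s = 0.0
                cnt = 0
                for n, p, _ in per_locus:
                    if n[t] == 0 or n[a] == 0 or n[b] == 0:
                        continue
                    cnt += 1
                    s += (p[t] - p[a]) * (p[t] - p[b])
                out[f"f3_{t}_{a}_{b}"] = s / cnt
    return out
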