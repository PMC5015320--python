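"""Independent brute-force evaluation used as the oracle in metric tests.

Everything here works on explicit Python sets materialized at every
threshold of the default grid, with none of the cumulative-count machinery
of the package implementation.
"""

import math

GRID = [k / 100.0 for k in range(1, 101)]


def pred_set(scores, tau):
    return {t for t, s in scores.items() if s >= tau}


def _eval_proteins(pred, truth, mode):
    proteins = sorted(truth)
    if mode == "partial":
        proteins = [p for p in proteins if pred.get(p)]
    return proteins


def brute_pr_rc(pred, truth, mode="full"):
    """Per-threshold (pr | None, rc, m) triples."""
    proteins = _eval_proteins(pred, truth, mode)
    n_e = len(proteins)
    out = []
    for tau in GRID:
        pr_terms = []
        rc_sum = 0.0
        for p in proteins:
            P = pred_set(pred.get(p, {}), tau)
            T = truth[p]
            if P:
                pr_terms.append(len(P & T) / len(P))
            rc_sum += len(P & T) / len(T)
        pr = sum(pr_terms) / len(pr_terms) if pr_terms else None
        out.append((pr, rc_sum / n_e, len(pr_terms)))
    return out


def brute_fmax(pred, truth, mode="full"):
    best = None
    for pr, rc, _m in brute_pr_rc(pred, truth, mode):
        if pr is None:
            continue
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if best is None or f > best:
            best = f
    return 0.0 if best is None else best


def brute_ru_mi(pred, truth, ic, mode="full"):
    proteins = _eval_proteins(pred, truth, mode)
    n_e = len(proteins)
    out = []
    for tau in GRID:
        ru = mi = 0.0
        for p in proteins:
            P = pred_set(pred.get(p, {}), tau)
            T = truth[p]
            ru += sum(ic[f] for f in T - P)
            mi += sum(ic[f] for f in P - T)
        out.append((ru / n_e, mi / n_e))
    return out


def brute_smin(pred, truth, ic, mode="full"):
    return min(
        math.sqrt(ru * ru + mi * mi) for ru, mi in brute_ru_mi(pred, truth, ic, mode)
    )


def brute_weighted_pr_rc(pred, truth, ic, mode="full"):
    proteins = _eval_proteins(pred, truth, mode)
    n_e = len(proteins)
    out = []
    for tau in GRID:
        pr_terms = []
        rc_sum = 0.0
        for p in proteins:
            P = pred_set(pred.get(p, {}), tau)
            T = truth[p]
            if P:
                denom = sum(ic[f] for f in P)
                pr_terms.append(
                    sum(ic[f] for f in P & T) / denom if denom > 0 else 0.0
                )
            t_ic = sum(ic[f] for f in T)
            if t_ic > 0:
                rc_sum += sum(ic[f] for f in P & T) / t_ic
        pr = sum(pr_terms) / len(pr_terms) if pr_terms else None
        out.append((pr, rc_sum / n_e))
    return out


def brute_weighted_fmax(pred, truth, ic, mode="full"):
    best = None
    for pr, rc in brute_weighted_pr_rc(pred, truth, ic, mode):
        if pr is None:
            continue
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if best is None or f > best:
            best = f
    return 0.0 if best is None else best


def brute_normalized_ru_mi(pred, truth, ic, mode="full"):
    proteins = _eval_proteins(pred, truth, mode)
    n_e = len(proteins)
    out = []
    for tau in GRID:
        ru = mi = 0.0
        for p in proteins:
            P = pred_set(pred.get(p, {}), tau)
            T = truth[p]
            denom = sum(ic[f] for f in P | T)
            if denom > 0:
                ru += sum(ic[f] for f in T - P) / denom
                mi += sum(ic[f] for f in P - T) / denom
        out.append((ru / n_e, mi / n_e))
    return out


def brute_normalized_smin(pred, truth, ic, mode="full"):
    return min(
        math.sqrt(ru * ru + mi * mi)
        for ru, mi in brute_normalized_ru_mi(pred, truth, ic, mode)
    )


def brute_coverage(pred, truth):
    return sum(1 for p in truth if pred.get(p)) / len(truth)


def brute_auc(pos_scores, neg_scores):
    """Exhaustive concordant-pair count with half-credit for ties."""
    total = 0.0
    for sp in pos_scores:
        for sn in neg_scores:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos_scores) * len(neg_scores))
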