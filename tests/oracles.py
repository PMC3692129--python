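"""Independent literal-loop oracles used by the test suite.

These re-derive quantities with straight nested loops and scalar maths,
deliberately sharing no code with the package implementation.
"""

import math


def pseudo_count_frequencies_loops(counts, t, T, m=5):
    """Pseudo-count smoothed frequencies, one index at a time."""
    n_types = len(counts)
    N = sum(counts)
    R = sum(1 for c in counts if c > 0)
    B = m * R
    g = [0.0] * n_types
    for a in range(n_types):
        for k in range(n_types):
            g[a] += (counts[k] / N) * (t[k][a] / T[k])
    gsum = sum(g)
    return [(counts[a] + B * g[a] / gsum) / (N + B)
            for a in range(n_types)]


def js_divergence_loops(f, bg):
    """Equal-weight Jensen-Shannon divergence, natural log."""
    out = 0.0
    for a in range(len(f)):
        mid = 0.5 * (f[a] + bg[a])
        if f[a] > 0:
            out += 0.5 * f[a] * math.log(f[a] / mid)
        if bg[a] > 0:
            out += 0.5 * bg[a] * math.log(bg[a] / mid)
    return out


def confusion_metrics_loops(predicted, truth, universe):
    """Confusion rates and statistics by explicit set membership tests."""
    tp = fp = tn = fn = 0
    for r in universe:
        p = r in predicted
        t = r in truth
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    n = len(universe)
    tp, fp, tn, fn = tp / n, fp / n, tn / n, fn / n
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "accuracy": tp + tn,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "mcc": mcc,
    }


def rmsd_loops(xs, ys):
    total = 0.0
    for x, y in zip(xs, ys):
        total += (x - y) ** 2
    return math.sqrt(total / len(xs))
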