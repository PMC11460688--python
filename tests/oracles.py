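"""Independent reference implementations used only by the test suite.

Each oracle is a deliberately naive transliteration of the textbook form of
an operation, kept separate from the package so that agreement between the
two is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def kendall_tau_bruteforce(x, y) -> float:
    """Tau-b by O(n^2) enumeration of concordant/discordant/tied pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    nc = nd = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2
    n1 = sum(t * (t - 1) // 2 for t in np.unique(x, return_counts=True)[1])
    n2 = sum(t * (t - 1) // 2 for t in np.unique(y, return_counts=True)[1])
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return 0.0
    return (nc - nd) / denom


def chi2_2x2_textbook(a, b, c, d) -> float:
    """Uncorrected 2x2 chi-square N(ad - bc)^2 / product-of-margins."""
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / margins


def relieff_textbook(X, y, m, k, sampled) -> np.ndarray:
    """Naive loop-based multi-class ReliefF on min-max scaled features.

    ``sampled`` is the sequence of instance indices to visit (the caller
    controls sampling so both implementations see the same instances).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span

    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    w = np.zeros(d)
    for i in sampled:
        dist = np.abs(Xs - Xs[i]).sum(axis=1)
        for c in classes:
            members = [j for j in range(n) if y[j] == c and j != i] if c == y[i] \
                else [j for j in range(n) if y[j] == c]
            members.sort(key=lambda j: (dist[j], j))
            near = members[:k]
            diff = np.mean([np.abs(Xs[j] - Xs[i]) for j in near], axis=0)
            if c == y[i]:
                w -= diff / m
            else:
                w += priors[c] / (1.0 - priors[y[i]]) * diff / m
    return w


def gwo_step_oracle(positions, leaders, a, draws):
    """Straight transliteration of the three-leader position update.

    ``draws`` must supply, per wolf and per leader in order, the r1 vector
    then the r2 vector (matching the package's documented draw order).
    A = 2a*r1 - a, C = 2*r2, D = |C*X_lead - X|, X' = X_lead - A*D;
    the new position is the average of the three, clamped to [0, 1].
    """
    pop, d = positions.shape
    out = np.zeros_like(positions)
    for i in range(pop):
        total = np.zeros(d)
        for lead in leaders:
            r1 = draws()
            r2 = draws()
            A = 2 * a * r1 - a
            C = 2 * r2
            D = np.abs(C * lead - positions[i])
            total = total + (lead - A * D)
        out[i] = total / 3.0
    return np.minimum(1.0, np.maximum(0.0, out))


def perturbed_step_oracle(positions, leaders, a, t, T, draws, scalar_draw):
    """Late-phase update: the averaged step scaled per wolf by Q = R*sigma + mean."""
    base_unclamped = np.zeros_like(positions)
    pop, d = positions.shape
    for i in range(pop):
        total = np.zeros(d)
        for lead in leaders:
            r1 = draws()
            r2 = draws()
            D = np.abs(2 * r2 * lead - positions[i])
            total = total + (lead - (2 * a * r1 - a) * D)
        base_unclamped[i] = total / 3.0
    base = np.minimum(1.0, np.maximum(0.0, base_unclamped))
    out = np.zeros_like(positions)
    for i in range(pop):
        R = math.sin(scalar_draw() * math.pi * t / T)
        sigma = positions[i].std()
        mean = positions[i].mean()
        q = R * sigma + mean
        out[i] = np.minimum(1.0, np.maximum(0.0, base[i] * q))
    return out


def vanilla_gwo_masks(d, evaluator, pop_size, T, seed):
    """Independent vanilla binary GWO sharing the package's draw-order and
    fitness contracts: linear a, no disturbance, oscillatory binarization.

    Returns (best_mask, best_fitness, history of best_fitness).
    """
    rng = np.random.default_rng(seed)
    positions = rng.random((pop_size, d))
    best_mask, best_fit = None, -np.inf
    history = []
    cache = {}
    for t in range(T):
        r = math.sin(rng.random() * math.pi) * math.exp(-t / T)
        fits = np.zeros(pop_size)
        masks = []
        for i in range(pop_size):
            mask = positions[i] > r
            if not mask.any():
                mask = np.zeros(d, dtype=bool)
                mask[int(np.argmax(positions[i]))] = True
            key = mask.tobytes()
            if key not in cache:
                cache[key] = evaluator(mask)
            acc = cache[key]
            wf = math.sin(math.pi / 2 * t / T)
            fits[i] = wf * acc + (1 - wf) * (1 - mask.sum() / d)
            masks.append(mask)
            if fits[i] > best_fit:
                best_fit = float(fits[i])
                best_mask = mask.copy()
        order = np.lexsort((np.arange(pop_size), -fits))[:3]
        leaders = [positions[i].copy() for i in order]
        a = 2.0 * (1.0 - t / T)
        new = np.zeros_like(positions)
        for i in range(pop_size):
            total = np.zeros(d)
            for lead in leaders:
                r1 = rng.random(d)
                r2 = rng.random(d)
                D = np.abs(2 * r2 * lead - positions[i])
                total = total + (lead - (2 * a * r1 - a) * D)
            new[i] = total / 3.0
        positions = np.clip(new, 0.0, 1.0)
        history.append(best_fit)
    return best_mask, best_fit, history


def centroid_cv_evaluator(table, labels, folds=5):
    """Light numpy nearest-centroid k-fold accuracy, for fast subset search
    in tests (deterministic contiguous folds after a fixed stratified order)."""
    X_all = table.values
    y = np.asarray(labels)
    order = np.argsort(y, kind="stable")  # stratify by interleaving classes
    order = order.reshape(-1)
    interleaved = np.concatenate(
        [order[i::len(np.unique(y))] for i in range(len(np.unique(y)))])
    fold_of = np.empty(len(y), dtype=int)
    fold_of[interleaved] = np.arange(len(y)) % folds
    classes = np.unique(y)

    def evaluate(mask):
        idx = np.flatnonzero(mask)
        X = X_all[:, idx]
        correct = 0
        for f in range(folds):
            test = fold_of == f
            cents = np.stack([X[~test][y[~test] == c].mean(axis=0)
                              for c in classes])
            d = ((X[test][:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
            pred = classes[np.argmin(d, axis=1)]
            correct += int((pred == y[test]).sum())
        return correct / len(y)

    return evaluate
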