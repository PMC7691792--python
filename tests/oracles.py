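"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the nonnegative-lasso
solver is plain projected ISTA, the fine-step simulator re-integrates the
inhibition dynamics from the defining update equation, and the matcher is a
greedy bipartite cosine matcher.
"""

import numpy as np


def ista_nonneg_lasso(s, phi, lam, n_iters=20000):
    """Projected ISTA for min_a 1/2||s - phi a||^2 + lam*sum(a), a >= 0."""
    L = np.linalg.norm(phi.T @ phi, 2)
    t = 1.0 / L
    a = np.zeros(phi.shape[1])
    for _ in range(n_iters):
        a = np.maximum(0.0, a - t * (phi.T @ (phi @ a - s)) - t * lam)
    return a


def fine_euler_lca(s, phi, lam, total_time, dt):
    """Direct Euler integration of du = (b - G~ T(u) - u) dt from u = 0."""
    b = phi.T @ s
    G = phi.T @ phi
    np.fill_diagonal(G, 0.0)
    u = np.zeros(phi.shape[1])
    n_steps = int(round(total_time / dt))
    for _ in range(n_steps):
        a = np.where(u > lam, u - lam, 0.0)
        u = u + dt * (b - G @ a - u)
    return np.where(u > lam, u - lam, 0.0)


def greedy_cosine_match(phi_true, phi_learned):
    """Greedy bipartite matching on |cosine|; returns matched similarities."""
    C = np.abs(phi_true.T @ phi_learned)
    matches, used_t, used_l = [], set(), set()
    order = np.dstack(np.unravel_index(np.argsort(-C, axis=None), C.shape))[0]
    for i, j in order:
        if i in used_t or j in used_l:
            continue
        used_t.add(i)
        used_l.add(j)
        matches.append(C[i, j])
        if len(matches) == min(C.shape):
            break
    return np.array(matches)


def nearest_prototype_labels(images, prototypes):
    """Classify each image by nearest (L2) prototype."""
    d2 = ((images[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)
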