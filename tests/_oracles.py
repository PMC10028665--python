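"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def dense_diffusion_oracle(a, n_components, alpha=0.5):
    """Dense diffusion-map oracle: explicit Markov operator and
    numpy.linalg.eig, multiscale lambda/(1-lambda) scaling, no
    symmetric-conjugate trick.

    Right eigenvectors are normalised to unit norm under the stationary
    distribution pi (so the trivial eigenvector is the constant 1), the
    standard diffusion-map convention.
    """
    a = np.asarray(a, dtype=float)
    d = a.sum(axis=1)
    w = a / np.outer(d**alpha, d**alpha)
    row = w.sum(axis=1)
    p = w / row[:, None]
    pi = row / row.sum()  # stationary distribution of the conjugate-symmetric P
    lams, vecs = np.linalg.eig(p)
    order = np.argsort(-lams.real)
    lams = lams.real[order]
    vecs = vecs.real[:, order]
    for k in range(vecs.shape[1]):
        vecs[:, k] /= np.sqrt(pi @ vecs[:, k] ** 2)
    vecs /= np.sign(vecs[0, 0]) if vecs[0, 0] != 0 else 1.0
    coords = vecs[:, 1 : n_components + 1] * (
        lams[1 : n_components + 1] / (1 - lams[1 : n_components + 1])
    )
    return lams, coords
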