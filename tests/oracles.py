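"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def rcs_basis_bruteforce(x, knots):
    """Naive, scalar-loop restricted truncated-power basis.

    Written directly from the defining formula, term by term, without any
    vectorisation or shared code with the package implementation.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = [float(k) for k in knots]
    k = len(t)
    out = np.zeros((len(x), k - 1))
    for i, xi in enumerate(x):
        out[i, 0] = xi
        for j in range(k - 2):
            def cube(knot):
                d = xi - knot
                return d ** 3 if d > 0 else 0.0
            term = (cube(t[j])
                    - cube(t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                    + cube(t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
            out[i, j + 1] = term / (t[k - 1] - t[0]) ** 2
    return out
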