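"""Independent brute-force oracles used by the test suite.

Deliberately coded against the raw likelihood definition, not against the
package's optimiser, so they stay an independent cross-check.
"""

import numpy as np

from pairedsse import joint_prob_bounds


def grid_argmin_nll(x, ma, mb, step=1e-6):
    """Exhaustive grid search of the constrained multinomial NLL.

    Evaluates -sum_i x_i log(base_i(p1)) on a dense grid over the closed
    feasible interval (bases clipped so zero-count factors never matter)
    and returns the grid point of minimum NLL.
    """
    b = joint_prob_bounds(ma, mb)
    grid = np.arange(b.lower, b.upper + step, step)
    grid = np.clip(grid, b.lower, b.upper)
    bases = np.stack([grid, ma - grid, mb - grid, 1.0 - ma - mb + grid])
    counts = np.asarray(x, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(np.clip(bases, 0.0, None))
        terms = np.where(counts > 0, -counts * logs, 0.0)
    nll = np.where(np.isnan(terms), np.inf, terms).sum(axis=0)
    return float(grid[int(np.argmin(nll))])
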