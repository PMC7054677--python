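import numpy as np
import pytest

from plaquekit.imgio import MultichannelSection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_section():
    """Two hard discs (r = 20 and 10 um) on a dark background, 0.5 um pixels."""
    px = 0.5
    n = 180
    yy, xx = np.mgrid[:n, :n] * px
    g8 = np.zeros((n, n))
    g8[np.hypot(xx - 27.0, yy - 27.0) <= 20.0] = 200.0
    g8[np.hypot(xx - 68.0, yy - 68.0) <= 10.0] = 200.0
    return MultichannelSection({"4G8": g8}, pixel_size_um=px)


def brute_force_otsu(counts, values):
    """Independent exhaustive Otsu oracle.

    Loops over every candidate threshold and recomputes both class means
    from scratch (no shared cumulative-sum machinery with the
    implementation); first maximiser wins, i.e. ties go to the lowest
    threshold.
    """
    counts = np.asarray(counts, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = counts > 0
    counts, values = counts[keep], values[keep]
    order = np.argsort(values)
    counts, values = counts[order], values[order]
    total = counts.sum()
    variances = []
    for k in range(len(values)):
        c0, c1 = counts[: k + 1], counts[k + 1 :]
        w0 = float(np.sum(c0)) / total
        w1 = 1.0 - w0
        if w1 <= 0:
            variances.append(0.0)
        else:
            mu0 = float(np.sum(c0 * values[: k + 1])) / (w0 * total)
            mu1 = float(np.sum(c1 * values[k + 1 :])) / (w1 * total)
            variances.append(w0 * w1 * (mu0 - mu1) ** 2)
    vmax = max(variances)
    for k, var in enumerate(variances):  # lowest threshold wins ties
        if var >= vmax - 1e-12 * max(vmax, 1e-300):
            return float(values[k])
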