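import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_cohort():
    """One small simulated cohort shared across tests (1.2 Mb, 64 samples,
    one planted sweep, two planted tracts, indels present)."""
    from cottonpop.sim import simulate_cohort
    from cottonpop.studies import pipeline_demo

    return simulate_cohort(pipeline_demo(3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Independent oracles (kept separate from the implementation code paths)


def pairwise_pi_oracle(genotypes: np.ndarray, span_bp: int) -> float:
    """O(n^2) average pairwise differences per site over all called allele
    pairs, divided by the full span length."""
    total = 0.0
    for row in genotypes:
        alleles = []
        for g in row:
            if g < 0:
                continue
            alleles.extend([1] * int(g) + [0] * (2 - int(g)))
        n = len(alleles)
        if n < 2:
            continue
        diff = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if alleles[i] != alleles[j]
        )
        total += diff / (n * (n - 1) / 2)
    return total / span_bp


def wc_components_oracle(ga: np.ndarray, gb: np.ndarray):
    """Direct scalar transcription of the Weir & Cockerham (1984)
    two-population a, b, c for one site of dosage genotypes."""
    def stats(g):
        g = [x for x in g if x >= 0]
        n = len(g)
        p = sum(g) / (2 * n)
        het = sum(1 for x in g if x == 1) / n
        return n, p, het

    n1, p1, h1 = stats(ga)
    n2, p2, h2 = stats(gb)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def interval_overlap_oracle(segments, max_gap):
    """One-pass sorted sweep merge oracle for same-key segments given as
    (start, end, n_sites) tuples; strict gap < max_gap merges."""
    if not segments:
        return []
    segs = sorted(segments)
    out = [list(segs[0])]
    for s, e, k in segs[1:]:
        if s - out[-1][1] < max_gap:
            out[-1][1] = max(out[-1][1], e)
            out[-1][2] += k
        else:
            out.append([s, e, k])
    return [tuple(x) for x in out]
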