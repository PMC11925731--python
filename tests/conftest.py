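import numpy as np
import pytest

from modcal.benchmark import apply_thresholds
from modcal.io_formats import KnownSite, SiteRecord
from modcal.synthetic import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim():
    """One full-profile synthetic dataset shared across the session."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_called(sim):
    """Called sets at the planted thresholds for both conditions."""
    a = apply_thresholds(sim.sites_a, sim.truth.thresholds)
    b = apply_thresholds(sim.sites_b, sim.truth.thresholds)
    return a, b


def random_called(rng, n_molecules=3, max_pos=60, density=0.3):
    """A random small called set for oracle comparisons."""
    called = set()
    for m in range(n_molecules):
        mol = f"m{m}"
        for pos in range(1, max_pos + 1):
            if rng.random() < density:
                called.add((mol, pos))
    return called


def random_known(rng, n_molecules=3, max_pos=60, n_sites=6):
    known = []
    seen = set()
    symbols = ["Ж", "P", "D", "?", "T", "4"]
    for _ in range(n_sites):
        mol = f"m{rng.integers(n_molecules)}"
        pos = int(rng.integers(1, max_pos + 1))
        if (mol, pos) in seen:
            continue
        seen.add((mol, pos))
        known.append(KnownSite(mol, pos, symbols[rng.integers(len(symbols))]))
    return known


def random_sites(rng, n=200, n_molecules=4, max_pos=80):
    """Random site records with threshold-straddling values."""
    sites = []
    seen = set()
    for _ in range(n):
        mol = f"m{rng.integers(n_molecules)}"
        pos = int(rng.integers(1, max_pos + 1))
        if (mol, pos) in seen:
            continue
        seen.add((mol, pos))
        sites.append(
            SiteRecord(
                mol, pos, "ACGU"[rng.integers(4)],
                esb_test=float(rng.choice([0.0, 0.05, 0.1, 0.3, 0.61])),
                esb_control=float(rng.choice([0.0, 0.005, 0.01, 0.02, 0.1])),
                odds_ratio=float(rng.choice([0.5, 1.5, 2.5, 3.0, 8.0])),
                p_adj=float(rng.choice([1e-8, 1e-5, 0.01, 0.05, 0.5, 1.0])),
                depth=int(rng.integers(0, 200)),
            )
        )
    return sites
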