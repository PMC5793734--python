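import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

from strucaln import synthetic_fixtures as sf  # noqa: E402


@pytest.fixture(scope="session")
def helix12():
    return sf.make_ideal_helix(12)


@pytest.fixture(scope="session")
def hairpin():
    return sf.make_beta_hairpin(6)


@pytest.fixture(scope="session")
def dimer_close():
    return sf.make_toy_dimer(gap=4.5)


@pytest.fixture(scope="session")
def ligand_close():
    return sf.make_toy_ligand_complex(dist=4.9)


@pytest.fixture(scope="session")
def toy_job():
    """4-row alignment (3 structures + 1 plain sequence) with noisy helices."""
    aln = sf.make_toy_alignment(4, 30, seed=1, conservation_profile="mixed",
                                with_structures=True, noise_sigma=0.3)
    last = aln.sequences[-1]
    last.role = "sequence"
    last.structure = None
    return aln


@pytest.fixture(scope="session")
def toy_document(toy_job):
    from strucaln.config import AnnotationParams
    from strucaln.pipeline import run_job
    return run_job(toy_job, AnnotationParams())


# ---------------------------------------------------------------- oracles

def brute_force_sasa(coords, radii, probe=1.4, n_points=6000, seed=1234):
    """Independent Shrake-Rupley oracle: seeded random directions, plain
    double loop, no spatial index."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    R = np.asarray(radii) + probe
    areas = []
    for i in range(len(coords)):
        sample = coords[i] + R[i] * pts
        keep = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            keep &= np.sum((sample - coords[j]) ** 2, axis=1) > R[j] ** 2
        areas.append(4 * np.pi * R[i] ** 2 * keep.sum() / n_points)
    return np.array(areas)


def brute_force_contacts(struct, cutoff):
    """All-pairs O(n² m²) contact oracle over heavy atoms."""
    n = len(struct.residues)
    out = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            found = False
            for a in struct.residues[i].atoms:
                for b in struct.residues[j].atoms:
                    if np.linalg.norm(a.coord - b.coord) <= cutoff:
                        found = True
                        break
                if found:
                    break
            if found:
                out[i].add(j)
                out[j].add(i)
    return out


def unweighted_kabsch_oracle(P, Q):
    """Plain SVD superposition of P onto Q, written independently."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc
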