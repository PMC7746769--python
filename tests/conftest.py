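import numpy as np
import pytest

from digesta.ion_io import IonTable, PeptideIon


def make_table(rows, source_id="S", replicate_id="r1"):
    """Build an IonTable from (mz, charge, rt, abundance) tuples."""
    ions = [
        PeptideIon(ion_id=i, mz=mz, charge=z, rt=rt, abundance=ab)
        for i, (mz, z, rt, ab) in enumerate(rows)
    ]
    return IonTable(source_id=source_id, replicate_id=replicate_id, ions=tuple(ions))


def random_dense_table(rng, n, source_id="S", replicate_id="r1",
                       mz_range=(500.0, 500.06), rt_range=(10.0, 11.0), charges=(1, 2)):
    """A table crowded enough that tolerance windows overlap heavily."""
    rows = [
        (
            rng.uniform(*mz_range),
            int(rng.choice(charges)),
            rng.uniform(*rt_range),
            float(rng.lognormal(12.0, 1.0)),
        )
        for _ in range(n)
    ]
    return make_table(rows, source_id=source_id, replicate_id=replicate_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def assert_family_constraints(fit, atol=1e-8):
    """Realized covariances must satisfy the family's equality structure."""
    fam = fit.spec.family
    covs = np.asarray(fit.covariances)
    k, d, _ = covs.shape
    eig = np.sort(np.linalg.eigvalsh(covs), axis=1)  # rows: per-component spectra
    scale = max(eig.max(), 1e-12)

    if fam.endswith("I"):  # diagonal orientation
        for j in range(k):
            off = covs[j] - np.diag(np.diag(covs[j]))
            assert np.abs(off).max() <= atol * scale, f"{fam}: non-diagonal Σ_{j}"
    if fam in ("EII", "VII"):  # spherical
        for j in range(k):
            diag = np.diag(covs[j])
            assert np.ptp(diag) <= atol * scale, f"{fam}: non-spherical Σ_{j}"
    if fam in ("EII", "EEI", "EEE", "EEV"):  # fully shared spectrum
        assert np.abs(eig - eig[0]).max() <= atol * scale, f"{fam}: spectra differ"
    if fam in ("EEE",):  # identical matrices
        assert np.abs(covs - covs[0]).max() <= atol * scale
    if fam[0] == "E" and fam not in ("EII", "EEI", "EEE", "EEV"):  # shared volume only
        vols = np.exp(np.log(eig).sum(axis=1) / d)
        assert np.ptp(vols) <= atol * max(vols.max(), 1e-12), f"{fam}: volumes differ"
    if fam[1] == "E" and fam[0] == "V" and fam != "VII":  # shared shape, varying volume
        vols = np.exp(np.log(eig).sum(axis=1) / d)
        shapes = eig / vols[:, None]
        assert np.abs(shapes - shapes[0]).max() <= atol, f"{fam}: shapes differ"
    if fam in ("EVE", "VVE", "VEE"):  # shared orientation: Σ_i Σ_j = Σ_j Σ_i
        for a in range(k):
            for b in range(a + 1, k):
                comm = covs[a] @ covs[b] - covs[b] @ covs[a]
                assert np.abs(comm).max() <= atol * scale ** 2, f"{fam}: orientations differ"
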