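import numpy as np
import pytest

from cmphelix import enumerate_library, fingerprint, palette, synth


@pytest.fixture(scope="session")
def full_palette():
    return palette.build_palette()


@pytest.fixture(scope="session")
def library_codes():
    return [s.hexamer_code for s in enumerate_library()]


@pytest.fixture(scope="session")
def library_embedding(library_codes):
    """Fingerprints + fitted 10-component embedding of the full library.

    Shared session-wide because fingerprinting 10 000 hexamers dominates the
    cost of every test that touches the real design space.
    """
    mols = [palette.sequence_to_molgraph(c) for c in library_codes]
    fps = fingerprint.fingerprint_matrix(mols)
    model = fingerprint.fit_embedding(fps)
    coords = fingerprint.embed_matrix(fps, model)
    return {"fps": fps, "model": model, "coords": coords}


@pytest.fixture(scope="session")
def small_landscape():
    """A 400-candidate sub-library with coordinates informative of latent Tm.

    Used by campaign-level tests that need a realistic but fast search
    problem: coordinate 0 carries the latent-Tm signal plus noise, the other
    nine dimensions are distractors.
    """
    codes = [s.hexamer_code for s in enumerate_library()]
    rng = np.random.default_rng(2024)
    idx = np.sort(rng.choice(len(codes), size=400, replace=False))
    codes = [codes[i] for i in idx]
    coords = rng.normal(size=(400, 10))
    lat = np.array([synth.latent_tm(c) for c in codes])
    coords[:, 0] = (lat - lat.mean()) / lat.std() + 0.1 * rng.normal(size=400)
    return codes, coords
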