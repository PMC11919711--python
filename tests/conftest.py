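import pytest

from casarray import assign_direct_repeats, random_spacers


@pytest.fixture(scope="session")
def spacer_pool():
    """60 random filter-clean 20-nt spacers."""
    return random_spacers(60, length=20, seed=11)


@pytest.fixture(scope="session")
def dr6():
    return assign_direct_repeats(6)


@pytest.fixture(scope="session")
def small_6plex_library(spacer_pool, dr6):
    """A 10-construct 6-plex library over a 30-spacer vocabulary."""
    from casarray import ConstructLibrary, assemble_array

    lib = ConstructLibrary()
    for i in range(10):
        spacers = spacer_pool[3 * i : 3 * i + 6]
        lib.add(assemble_array(spacers, dr6, construct_id=f"c{i:02d}"))
    return lib
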