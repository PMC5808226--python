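import numpy as np
import pytest

from aquapore.swelling import AssayConstants, SwellingTrace


@pytest.fixture
def constants() -> AssayConstants:
    """Standard oocyte assay constants (V0, S, Vw, Osm_in, Osm_out)."""
    return AssayConstants()


def make_trace(times, rel_area, **kwargs) -> SwellingTrace:
    defaults = dict(oocyte_id="t", group="expressing", condition="water")
    defaults.update(kwargs)
    return SwellingTrace(times=np.asarray(times, float),
                         rel_area=np.asarray(rel_area, float), **defaults)
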