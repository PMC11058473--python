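import pytest

from atf4queue import build_reference_leader, SimulationParams
from atf4queue.scanner import annotate_leader


@pytest.fixture(scope="session")
def reference():
    """The packaged ATF4-like leader (built once per session)."""
    return build_reference_leader()


@pytest.fixture(scope="session")
def fast_params():
    """Cheap parameter set for engine unit tests."""
    return SimulationParams(k_load=0.2, p_tc_at_load=0.0, k_tc=1.0)


def make_toy_leader(uorf_codons=2, spacer=16, p_rei=None, hairpin=False, name="toy"):
    """A small leader: optional short uORF at 35, optional perfect hairpin,
    main AUG near the end.  All elements sit past the cap-loading P-site."""
    seq = "ACACAC" * 5  # 30 nt of inert leader
    parts = [seq]
    pos = len(seq) + 1
    uorf_start = None
    if uorf_codons:
        uorf_start = pos
        parts.append("AUG" + "CAA" * uorf_codons + "UAA")
        pos += 3 * (uorf_codons + 2)
    parts.append("ACACAC"[: spacer % 6] + "AC" * (spacer // 2))
    pos += spacer % 6 + 2 * (spacer // 2)
    if hairpin:
        parts.append("GGCGGC" + "AAAA" + "GCCGCC")
        pos += 16
        parts.append("ACACAC")
        pos += 6
    cds = pos
    parts.append("AUG" + "CAACAUCAACAUCAACAU")
    seq = "".join(parts)
    return annotate_leader(seq, cds, name=name), uorf_start, cds
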