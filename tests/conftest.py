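import random

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from mdresim.seqmodel import IUPAC_CLASSES, MethylatedDuplex, ModType

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------- hypothesis strategies ----------

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


@st.composite
def duplexes(draw, min_size=1, max_size=80, circular=None, with_label=False):
    seq = draw(st.text(alphabet="ACGT", min_size=min_size, max_size=max_size))
    topo = draw(st.sampled_from(["linear", "circular"])) if circular is None else (
        "circular" if circular else "linear")
    c_pos = [i for i, b in enumerate(seq) if b == "C"]
    g_pos = [i for i, b in enumerate(seq) if b == "G"]
    top = {i: draw(st.sampled_from(list(ModType)))
           for i in draw(st.sets(st.sampled_from(c_pos)) if c_pos else st.just(set()))}
    bottom = {i: draw(st.sampled_from(list(ModType)))
              for i in draw(st.sets(st.sampled_from(g_pos)) if g_pos else st.just(set()))}
    label = None
    if with_label and draw(st.booleans()):
        from mdresim.seqmodel import StrandLabel
        label = StrandLabel(draw(st.sampled_from(["top", "bottom"])),
                            draw(st.sampled_from(["5prime", "3prime"])), "FAM")
    return MethylatedDuplex(seq, topo, top, bottom, label)


# ---------- independent oracles ----------

def naive_find_sites(d: MethylatedDuplex, pattern: str):
    """O(L*|P|) double-strand scanner, written independently of the package
    implementation: explicit IUPAC set checks over a doubled string."""
    L, n = len(d.seq), len(pattern)
    if n > L:
        return []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    ext = d.seq + d.seq if d.circular else d.seq
    starts = range(L) if d.circular else range(L - n + 1)
    hits = []
    for s in starts:
        window = ext[s : s + n]
        if all(b in IUPAC_CLASSES[c] for c, b in zip(pattern, window)):
            hits.append((s, "top"))
        bottom_window = "".join(comp[b] for b in reversed(window))
        if all(b in IUPAC_CLASSES[c] for c, b in zip(pattern, bottom_window)):
            hits.append((s, "bottom"))
    return hits


def plant_site(seq: str, motif_pattern: str, pos: int, rng: random.Random) -> str:
    """Replace seq[pos:pos+n] with a concrete instance of an IUPAC pattern."""
    inst = "".join(rng.choice(sorted(IUPAC_CLASSES[c])) for c in motif_pattern)
    return seq[:pos] + inst + seq[pos + len(inst):]


@pytest.fixture
def oligos():
    from mdresim.fixtures import oligo_fixtures
    return oligo_fixtures()
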