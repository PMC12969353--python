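import pytest

from oripool.parts import LibraryDesign, Part

FLANK_L = "CAGTGAACTGGACTTCAGCA"
FLANK_R = "TCCTGAAGTCGACCATGGAT"


def _body(seed: int, n: int) -> str:
    # deterministic pseudo-random DNA without touching global RNG state
    bases = "ACGT"
    x = seed * 2654435761 % 2**32
    out = []
    for _ in range(n):
        x = (1103515245 * x + 12345) % 2**31
        out.append(bases[x % 4])
    return "".join(out)


@pytest.fixture(scope="session")
def tiny_design() -> LibraryDesign:
    """A minimal 2x2x1 design with chained overhangs o1..o4."""
    o1, o2, o3, o4 = "AATT", "CCGG", "GATC", "TTAA"
    backbone_body = _body(9, 120) + FLANK_L + FLANK_R + _body(10, 120)
    return LibraryDesign(
        parts_by_category={
            "origin": [
                Part("oriA", "origin", _body(1, 300), o4, o1),
                Part("oriB", "origin", _body(2, 300), o4, o1),
            ],
            "promoter": [
                Part("pA", "promoter", _body(3, 150), o1, o2),
                Part("pB", "promoter", _body(4, 150), o1, o2),
            ],
            "resistance": [Part("kanA", "resistance", _body(5, 400), o2, o3)],
            "backbone": [Part("bb", "backbone", backbone_body, o3, o4)],
        },
        flank_left=FLANK_L,
        flank_right=FLANK_R,
        barcode_length=20,
    )


@pytest.fixture()
def tiny_selection() -> dict:
    return {"origin": "oriA", "promoter": "pA", "resistance": "kanA"}
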