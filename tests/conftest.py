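import pytest

from majplus import Profile, parse_newick


def rt(newick: str):
    """Rooted tree from Newick."""
    return parse_newick(newick, rooted=True)


def ut(newick: str):
    """Unrooted tree from Newick."""
    return parse_newick(newick, rooted=False)


def rprofile(*newicks):
    return Profile(tuple(rt(nw) for nw in newicks), rooted=True)


def uprofile(*newicks):
    return Profile(tuple(ut(nw) for nw in newicks), rooted=False)


@pytest.fixture
def quartet_conflict():
    """Two maximally conflicting quartets on one leaf set."""
    return uprofile("((a,b),(c,d));", "((a,c),(b,d));")
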