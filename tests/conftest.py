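import itertools

import pytest

from phylodecay import read_newick


def all_binary_topologies(labels):
    """Yield every rooted binary labelled topology over ``labels`` as Newick.

    Recursive bipartition enumeration: the first label is pinned to the
    left block to avoid counting mirror splits twice.  Counts follow the
    double factorial (2n-3)!!: 1, 3, 15, 105, 945 for n = 2..6.
    """
    labels = list(labels)
    if len(labels) == 1:
        yield labels[0] + ":1"
        return
    first, rest = labels[0], labels[1:]
    for r in range(len(rest)):
        for right in itertools.combinations(rest, r + 1):
            left = [first] + [x for x in rest if x not in right]
            for lsub in all_binary_topologies(left):
                for rsub in all_binary_topologies(list(right)):
                    yield f"({lsub},{rsub}):1"


def topology_trees(n):
    names = [chr(ord("A") + i) for i in range(n)]
    for nwk in all_binary_topologies(names):
        yield read_newick(nwk + ";")


@pytest.fixture
def three_tip():
    return read_newick("((A:5,B:5):10,C:15);")


@pytest.fixture
def four_tip_balanced():
    return read_newick("((A:2,B:2):3,(C:2,D:2):3);")


@pytest.fixture
def caterpillar4():
    return read_newick("(((A:1,B:1):1,C:2):1,D:3);")
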