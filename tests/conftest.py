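from __future__ import annotations

import stat
import textwrap

import numpy as np
import pytest

from alnvalid import DistanceMatrix


@pytest.fixture
def worked_matrix() -> tuple[DistanceMatrix, dict[str, str]]:
    """Two 2-member families with small within- and large between-distances;
    silhouettes are computable by hand."""
    d = DistanceMatrix(
        ["s1", "s2", "s3", "s4"],
        np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 0.7, 0.8],
                [0.8, 0.7, 0.0, 0.2],
                [0.9, 0.8, 0.2, 0.0],
            ]
        ),
    )
    labels = {"s1": "famA", "s2": "famA", "s3": "famB", "s4": "famB"}
    return d, labels


def _write_script(path, body: str) -> str:
    path.write_text(textwrap.dedent(body))
    path.chmod(path.stat().st_mode | stat.S_IXUSR)
    return str(path)


@pytest.fixture(scope="session")
def stub_aligner(tmp_path_factory) -> str:
    """A fake MSA program: pads every sequence with trailing gaps to a common
    length and prints the aligned FASTA to stdout."""
    path = tmp_path_factory.mktemp("tools") / "stub_aligner.py"
    return _write_script(
        path,
        """\
        #!/usr/bin/env python
        import sys

        recs, cur = [], None
        with open(sys.argv[1]) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    cur = [line[1:].split()[0], ""]
                    recs.append(cur)
                elif line:
                    cur[1] += line
        L = max(len(s) for _, s in recs)
        for name, s in recs:
            print(">" + name)
            print(s + "-" * (L - len(s)))
        """,
    )


@pytest.fixture(scope="session")
def shuffling_aligner(tmp_path_factory) -> str:
    """A deliberately corrupted aligner: scatters each row's gaps at random
    positions (fixed seed), destroying column homology while leaving every
    row degappable to its input sequence."""
    path = tmp_path_factory.mktemp("tools") / "shuffling_aligner.py"
    return _write_script(
        path,
        """\
        #!/usr/bin/env python
        import random
        import sys

        recs, cur = [], None
        with open(sys.argv[1]) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    cur = [line[1:].split()[0], ""]
                    recs.append(cur)
                elif line:
                    cur[1] += line
        L = max(len(s) for _, s in recs) + 20
        rng = random.Random(1234)
        for name, s in recs:
            cols = ["-"] * L
            for pos, ch in zip(sorted(rng.sample(range(L), len(s))), s):
                cols[pos] = ch
            print(">" + name)
            print("".join(cols))
        """,
    )


@pytest.fixture(scope="session")
def dropping_aligner(tmp_path_factory) -> str:
    """A broken aligner that silently drops the first sequence."""
    path = tmp_path_factory.mktemp("tools") / "dropping_aligner.py"
    return _write_script(
        path,
        """\
        #!/usr/bin/env python
        import sys

        recs, cur = [], None
        with open(sys.argv[1]) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    cur = [line[1:].split()[0], ""]
                    recs.append(cur)
                elif line:
                    cur[1] += line
        L = max(len(s) for _, s in recs)
        for name, s in recs[1:]:
            print(">" + name)
            print(s + "-" * (L - len(s)))
        """,
    )


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write (id, sequence) pairs to a FASTA file under tmp_path."""

    def _write(name: str, records: list[tuple[str, str]]) -> str:
        p = tmp_path / name
        p.write_text("".join(f">{i}\n{s}\n" for i, s in records))
        return str(p)

    return _write
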