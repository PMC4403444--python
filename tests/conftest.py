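import numpy as np
import pandas as pd
import pytest

from corego.formats_io import CountMatrix


@pytest.fixture
def tiny_counts():
    counts = pd.DataFrame(
        {"s1": [10, 5], "s2": [0, 7]},
        index=pd.Index(["geneA", "geneB"], name="gene_id"),
        dtype=np.int64,
    )
    design = pd.DataFrame(
        {"condition": ["WT", "KO"], "replicate": [1, 1]},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return CountMatrix(counts=counts, design=design)


@pytest.fixture
def random_counts():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(
        rng.integers(0, 1000, size=(50, 6)),
        index=pd.Index([f"g{i}" for i in range(50)], name="gene_id"),
        columns=[f"s{j}" for j in range(6)],
        dtype=np.int64,
    )
    design = pd.DataFrame(
        {"condition": ["A", "A", "A", "B", "B", "B"], "replicate": [1, 2, 3, 1, 2, 3]},
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts=counts, design=design)


@pytest.fixture
def toy_gtf(tmp_path):
    """10 genes, alternating strands, 3 lincRNAs, one gene without biotype."""
    lines = []
    for i in range(10):
        start1 = 1001 + 5000 * i
        end1 = start1 + 999
        strand = "+" if i % 2 == 0 else "-"
        if i in (2, 5, 8):
            bt = ' gene_biotype "lincRNA";'
        elif i == 9:
            bt = ""  # defaults to protein_coding
        else:
            bt = ' gene_biotype "protein_coding";'
        lines.append(
            f"chr1\ttest\tgene\t{start1}\t{end1}\t.\t{strand}\t.\t"
            f'gene_id "g{i}";{bt}\n'
        )
    path = tmp_path / "toy.gtf"
    path.write_text("".join(lines))
    return path
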