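import numpy as np
import pandas as pd
import pytest

from dmrkit import FeatureAnnotation, MethylomeTrack, build_genome


def make_track(rows, **meta) -> MethylomeTrack:
    """Track from (chrom, pos, strand, context, n_meth, n_unmeth) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )
    return MethylomeTrack(df, **meta)


def make_annotation(rows) -> FeatureAnnotation:
    """Annotation from (chrom, start, end, feature_class, feature_id) tuples."""
    return FeatureAnnotation(
        pd.DataFrame(
            rows, columns=["chrom", "start", "end", "feature_class", "feature_id"]
        )
    )


def random_track(rng: np.random.Generator, n: int, span: int = 5000) -> MethylomeTrack:
    """A random small track: unique positions, mixed contexts and coverages.

    Strand and context are deterministic functions of position, as they would
    be for cytosines of a real reference, so independently drawn tracks stay
    mutually consistent (poolable).
    """
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=min(n, span), replace=False))
    cov = rng.poisson(8, size=len(pos))
    meth = rng.binomial(cov, rng.uniform(0, 1, size=len(pos)))
    contexts = np.array(["CG", "CHG", "CHH"])[pos % 3]
    strands = np.array(["+", "-"])[pos % 2]
    return make_track(
        list(zip(["chr1"] * len(pos), pos, strands, contexts, meth, cov - meth))
    )


@pytest.fixture(scope="session")
def small_genome():
    """A 150-kb synthetic genome shared by tests that only need structure."""
    return build_genome(11, {"chr1": 150_000})
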