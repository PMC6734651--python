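import numpy as np
import pandas as pd
import pytest

from boolmark import StudyConfig, generate_expression


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """Reduced-scale study used by several module tests."""
    return StudyConfig(
        n_crc=300, n_polyp=10, n_ibd=40, n_normal=40,
        n_genes=100, n_bimodal=10, n_de=5,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_expression(small_config, seed=11)


@pytest.fixture()
def expression_tsv(tmp_path):
    """Write a tiny genes x samples TSV and return its path."""

    def _write(rows: list[str], name: str = "expr.tsv"):
        path = tmp_path / name
        path.write_text("\n".join(rows) + "\n")
        return path

    return _write


def brute_force_step_sse(values: np.ndarray) -> tuple[int, float]:
    """Independent oracle: enumerate every breakpoint of the sorted vector and
    return (best 1-based left-segment size, minimal SSE), ties to smallest."""
    s = np.sort(np.asarray(values, dtype=float))
    n = s.size
    best_i, best_sse = None, np.inf
    for i in range(1, n):
        left, right = s[:i], s[i:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best_sse - 1e-12:
            best_i, best_sse = i, sse
    return best_i, best_sse
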