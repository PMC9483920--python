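import warnings

import pytest

from salrshell.model import ShellGeometry


def quiet_shell(r_inn: float, r_out: float) -> ShellGeometry:
    """ShellGeometry without the narrow-inner-radius warning noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ShellGeometry(r_inn, r_out)


@pytest.fixture(scope="session")
def shell_6_11() -> ShellGeometry:
    return ShellGeometry(6.0, 11.0)


@pytest.fixture(scope="session")
def decorated_suite():
    """Decorated worked-example suite with cluster analysis, computed once
    per session (used by fixture recovery and acceptance tests)."""
    from salrshell.clusters import build_clusters
    from salrshell.fixtures import decorate, worked_example_suite

    out = []
    for entry in worked_example_suite(seed=3):
        cfg = decorate(entry.spec, entry.shell)
        cs = build_clusters(cfg)
        cs.classify()
        out.append((entry, cfg, cs))
    return out
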