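import sys
from pathlib import Path

import pytest

# make the frozen reference tables importable from any test module
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def paired_csv(tmp_path):
    """Factory writing a small two-column delimited file."""

    def make(rows, name="data.csv", sep=",", header=None):
        lines = []
        if header:
            lines.append(sep.join(header))
        for row in rows:
            lines.append(sep.join("" if v is None else str(v) for v in row))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return make
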