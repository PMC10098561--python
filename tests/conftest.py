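import numpy as np
import pytest

from emg_gmdh import SignalFrame

# 16-sample, 8-channel excerpt of the physical-action EMG recordings
# (biceps/triceps/thigh/hamstring pairs), used as a tiny real-data fixture.
TABLE4_TEXT = """\
-8.3532 2.5062 -2.406 -1.821 -1.1889 0.39931 -9.4774 -2.199
-7.073 2.1373 -2.6182 -2.0345 -1.3689 1.0842 -8.8761 -1.4746
-7.6434 2.3723 -2.4497 -2.2773 -1.4443 2.2408 -9.8723 -1.0962
-8.0995 2.4517 -2.7688 -2.4155 -1.4903 1.8016 -9.8628 -1.1314
-8.3307 2.3913 -3.0164 -2.1852 -1.394 0.44444 -9.9628 -1.2333
-8.7935 2.8082 -2.7473 -1.9383 -1.3229 1.0435 -9.7058 -1.2769
-8.9454 2.8268 -2.7351 -1.6787 -1.1889 1.8488 -9.6066 -1.2535
-9.4027 2.9628 -2.6491 -1.4568 -1.0424 1.6883 -9.5739 -0.95139
-8.9815 3.116 -2.4038 -1.4401 -1.0382 1.2073 -10.205 -0.69609
-9.1775 2.8138 -2.6836 -1.4903 -1.0173 1.1904 -10.231 -0.37467
-8.64 2.7076 -2.63 -1.4819 -0.90424 1.2918 -9.992 -0.19502
-8.7625 3.7808 -3.0071 -1.0717 -0.55259 1.8689 -9.5166 -0.17589
-8.5805 3.7717 -2.9237 -0.7619 -0.40607 1.9708 -9.4467 -0.1193
-8.6582 3.6193 -2.9164 -0.51073 -0.20513 1.7172 -9.9153 -0.43692
-8.6379 3.6099 -2.9593 -0.29304 -0.029304 1.2985 -9.9256 -0.4833
-8.4253 3.5899 -2.7716 -0.15489 0.066981 1.0929 -9.9872 -0.69676
"""

TABLE4_DATA = np.array(
    [[float(tok) for tok in line.split()] for line in TABLE4_TEXT.strip().splitlines()]
)


@pytest.fixture(scope="session")
def table4_text() -> str:
    return TABLE4_TEXT


@pytest.fixture
def table4_frame() -> SignalFrame:
    return SignalFrame(TABLE4_DATA.copy())


@pytest.fixture
def table4_file(tmp_path, table4_text):
    path = tmp_path / "table4.txt"
    path.write_text(table4_text)
    return path


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
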