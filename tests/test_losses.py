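"""Loss-function correctness against independently coded oracles, plus
schedule arithmetic and finite-difference gradient checks."""

import math

import numpy as np
import pytest

from phenoclip.autodiff import Tensor
from phenoclip.losses import (LossWeights, adversarial_weight, focal_clip_loss,
                              modality_loss, positivity_loss, total_loss)


# ---------------------------------------------------------------------------
# independent oracles (no code shared with the implementation)
# ---------------------------------------------------------------------------

def oracle_focal_clip(i_rows, t_rows, gamma, tau):
    """Element-by-element evaluation of the focal CLIP recipe using plain
    Python loops and math functions."""
    n, d = len(i_rows), len(i_rows[0])

    def norm(row):
        s = math.sqrt(sum(v * v for v in row) + 1e-8)
        return [v / s for v in row]

    i_n = [norm(r) for r in i_rows]
    t_n = [norm(r) for r in t_rows]
    s = [[sum(i_n[a][k] * t_n[b][k] for k in range(d)) / tau for b in range(n)]
         for a in range(n)]

    def focal_nll(rows):
        total = 0.0
        for y, row in enumerate(rows):
            m = max(row)
            exps = [math.exp(v - m) for v in row]
            p = exps[y] / sum(exps)
            total += (1.0 - p) ** gamma * (-math.log(max(p, 1e-8)))
        return total / n

    s_t = [[s[b][a] for b in range(n)] for a in range(n)]
    return 0.5 * (focal_nll(s) + focal_nll(s_t))


def oracle_bce(scores, targets, smoothing):
    out = []
    for p, t in zip(scores, targets):
        ts = t * (1.0 - smoothing) + smoothing / 2.0
        p = min(max(p, 1e-6), 1.0 - 1e-6)
        out.append(-(ts * math.log(p) + (1.0 - ts) * math.log(1.0 - p)))
    return out


# ---------------------------------------------------------------------------
# focal CLIP loss
# ---------------------------------------------------------------------------

class TestFocalClip:
    def test_single_pair_loss_is_exactly_zero(self):
        i = np.array([[1.0, 2.0, 3.0]])
        assert focal_clip_loss(i, i * 2.0, gamma=2.0, tau=0.1).item() == 0.0

    def test_gamma_zero_equals_plain_symmetric_clip(self):
        rng = np.random.default_rng(0)
        i = rng.normal(size=(5, 8))
        t = rng.normal(size=(5, 8))
        # separately coded plain CLIP cross-entropy
        i_n = i / np.linalg.norm(i, axis=1, keepdims=True)
        t_n = t / np.linalg.norm(t, axis=1, keepdims=True)
        s = i_n @ t_n.T / 0.2

        def xent(logits):
            logp = logits - np.log(np.exp(logits - logits.max(1, keepdims=True))
                                   .sum(1, keepdims=True)) - logits.max(1, keepdims=True)
            return -np.mean(np.diag(logp))

        expected = 0.5 * (xent(s) + xent(s.T))
        assert abs(focal_clip_loss(i, t, gamma=0.0, tau=0.2).item()
                   - expected) < 1e-8

    @pytest.mark.parametrize("trial", range(5))
    def test_random_instances_match_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 9))
        d = int(rng.integers(2, 17))
        gamma = float(rng.choice([0.5, 1.0, 2.0]))
        tau = float(rng.uniform(0.05, 1.0))
        i = rng.normal(size=(n, d))
        t = rng.normal(size=(n, d))
        ours = focal_clip_loss(i, t, gamma=gamma, tau=tau).item()
        expected = oracle_focal_clip(i.tolist(), t.tolist(), gamma, tau)
        assert abs(ours - expected) / max(abs(expected), 1e-12) < 1e-6

    def test_symmetric_under_joint_row_permutation(self):
        rng = np.random.default_rng(1)
        i = rng.normal(size=(6, 4))
        t = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        a = focal_clip_loss(i, t, gamma=2.0, tau=0.1).item()
        b = focal_clip_loss(i[perm], t[perm], gamma=2.0, tau=0.1).item()
        assert abs(a - b) < 1e-10

    def test_focal_weighting_never_exceeds_unweighted_loss(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            i = rng.normal(size=(4, 6))
            t = rng.normal(size=(4, 6))
            assert focal_clip_loss(i, t, gamma=2.0, tau=0.1).item() <= \
                focal_clip_loss(i, t, gamma=0.0, tau=0.1).item() + 1e-12

    def test_rejects_nonpositive_temperature(self):
        i = np.ones((2, 3))
        with pytest.raises(ValueError):
            focal_clip_loss(i, i, gamma=2.0, tau=0.0)


# ---------------------------------------------------------------------------
# positivity BCE
# ---------------------------------------------------------------------------

class TestPositivityLoss:
    def test_scores_equal_to_smoothed_targets_give_target_entropy(self):
        s = 0.2
        targets = np.array([[0.0, 1.0, 1.0, 0.0]])
        smoothed = targets * (1 - s) + s / 2
        loss = positivity_loss(smoothed.astype(np.float64), targets,
                               np.ones_like(targets), smoothing=s).item()
        entropy = float(np.mean(-(smoothed * np.log(smoothed)
                                  + (1 - smoothed) * np.log(1 - smoothed))))
        assert abs(loss - entropy) < 1e-9

    def test_perfect_binary_predictions_with_no_smoothing_vanish(self):
        targets = np.array([[0.0, 1.0, 1.0]])
        loss = positivity_loss(targets.copy(), targets, np.ones_like(targets),
                               smoothing=0.0).item()
        assert loss < 1e-5

    def test_random_case_matches_per_element_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0.01, 0.99, size=(3, 4))
        targets = rng.integers(0, 2, size=(3, 4)).astype(float)
        mask = np.ones((3, 4))
        mask[1, 2] = 0.0
        ours = positivity_loss(scores, targets, mask, smoothing=0.2).item()
        per_elem = oracle_bce(scores.ravel(), targets.ravel(), 0.2)
        keep = mask.ravel().astype(bool)
        expected = float(np.mean(np.asarray(per_elem)[keep]))
        assert abs(ours - expected) < 1e-9

    def test_no_labeled_channels_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            loss = positivity_loss(np.ones((2, 3)) * 0.5, np.zeros((2, 3)),
                                   np.zeros((2, 3)))
        assert loss.item() == 0.0


# ---------------------------------------------------------------------------
# schedule and total
# ---------------------------------------------------------------------------

class TestSchedule:
    def test_quartic_root_ramp_values(self):
        w = 0.37
        assert adversarial_weight(0, w) == 0.0
        assert adversarial_weight(1, w) == w
        assert abs(adversarial_weight(16, w) - 2.0 * w) < 1e-15

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            adversarial_weight(-1, 0.1)

    def test_weights_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            LossWeights(w_cls=-1.0)


class TestTotalLoss:
    def scalar(self, v):
        return Tensor(np.asarray(float(v)))

    def test_all_zero_weights_give_zero(self):
        w = LossWeights(w_cls=0.0, w_pos=0.0, w_adv_base=0.0)
        total, _ = total_loss(self.scalar(3.0), self.scalar(1.0),
                              self.scalar(2.0), w, epoch=5)
        assert total.item() == 0.0

    def test_single_term_configs_reproduce_components(self):
        total, _ = total_loss(self.scalar(3.0), self.scalar(1.0), None,
                              LossWeights(w_cls=1.0, w_pos=0.0), epoch=2)
        assert total.item() == 3.0

    def test_randomized_weighted_sum_matches_arithmetic(self):
        rng = np.random.default_rng(4)
        lc, lp, la = rng.uniform(0, 3, size=3)
        w = LossWeights(w_cls=0.7, w_pos=1.3, w_adv_base=0.2)
        epoch = 7
        total, breakdown = total_loss(self.scalar(lc), self.scalar(lp),
                                      self.scalar(la), w, epoch=epoch)
        expected = 0.7 * lc + 1.3 * lp + 0.2 * epoch ** 0.25 * la
        assert abs(total.item() - expected) < 1e-12
        assert abs(breakdown["w_adv"] - 0.2 * epoch ** 0.25) < 1e-15

    def test_nan_term_aborts_with_term_identified(self):
        with pytest.raises(FloatingPointError, match="loss_pos"):
            total_loss(self.scalar(1.0), self.scalar(np.nan), None,
                       LossWeights(), epoch=1)


# ---------------------------------------------------------------------------
# analytic gradients vs central finite differences
# ---------------------------------------------------------------------------

def fd_grad(fn, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = fn()
        arr[idx] = orig - eps
        fm = fn()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestLossGradients:
    def test_focal_clip_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        i = rng.normal(size=(4, 6))
        t = rng.normal(size=(4, 6))
        log_tau = np.array(np.log(0.1))
        ti = Tensor(i, requires_grad=True)
        tt = Tensor(t, requires_grad=True)
        tl = Tensor(log_tau, requires_grad=True)
        focal_clip_loss(ti, tt, gamma=2.0, tau=tl.exp()).backward()
        for tensor, arr in ((ti, i), (tt, t), (tl, log_tau)):
            num = fd_grad(lambda: focal_clip_loss(
                Tensor(i), Tensor(t), gamma=2.0,
                tau=Tensor(log_tau).exp()).item(), arr)
            scale = np.abs(num).max() + 1e-12
            assert np.abs(num - tensor.grad).max() / scale < 1e-4

    def test_positivity_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(0.05, 0.95, size=(3, 5))
        targets = rng.integers(0, 2, size=(3, 5)).astype(float)
        mask = np.ones((3, 5))
        ts = Tensor(scores, requires_grad=True)
        positivity_loss(ts, targets, mask, smoothing=0.2).backward()
        num = fd_grad(lambda: positivity_loss(Tensor(scores), targets, mask,
                                              smoothing=0.2).item(), scores)
        assert np.abs(num - ts.grad).max() / np.abs(num).max() < 1e-4

    def test_modality_ce_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        logits = rng.normal(size=(4, 3))
        targets = np.array([0, 2, 1, 1])
        tl = Tensor(logits, requires_grad=True)
        modality_loss(tl, targets, smoothing=0.01).backward()
        num = fd_grad(lambda: modality_loss(Tensor(logits), targets,
                                            smoothing=0.01).item(), logits)
        assert np.abs(num - tl.grad).max() / np.abs(num).max() < 1e-4
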