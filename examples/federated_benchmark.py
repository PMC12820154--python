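"""The packaged federated benchmark: FedAvg vs FedProx + LoRA.

Pretrains the tiny backbone on a synthetic source domain, then runs two
strategy arms over 10 non-IID clients for 10 communication rounds and prints
the per-round global accuracy and communication payloads.  Expect the
full-model FedAvg arm to degrade under client drift while the FedProx + LoRA
arm stays stable at a ~38x smaller payload.
"""

from fedlora import convergence_rounds
from fedlora.benchmark import run_benchmark

results = run_benchmark(strategies=("fedavg", "fedprox_lora"), seed=0, rounds=10)

for name, state in results.items():
    accs = [h.accuracy for h in state.history]
    per_client_kib = state.history[0].uplink_bytes / len(state.history[0].selected_clients) / 1024
    conv = convergence_rounds(state.history, "accuracy", 0.9)
    print(f"{name}:")
    print("  accuracy by round:", " ".join(f"{a:.3f}" for a in accs))
    print(f"  final accuracy {accs[-1]:.3f}; rounds to reach 0.90: {conv}")
    print(f"  per-client uplink payload: {per_client_kib:.1f} KiB/round")
    print()
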