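# actseg

Iterative point-cloud segmentation and registration of 3D medical volumes
with an actor/value action-learning agent.

A surface mesh (or landmark cloud) is moved inside a volume by a sequence of
actions — rigid translation, anisotropic scale, rotation (9 affine degrees of
freedom) and a smooth per-vertex deformation. An **actor network** proposes
one candidate per action type from a per-vertex observation encoding (image
intensities sampled in world mm along vertex normals, or as sub-volume
patches, plus unit-sphere-normalized point coordinates); a **value network**
scores each candidate's Q-value and the argmax action is applied, until the
best Q drops below a threshold or a step limit is reached.

Training combines:

- an **analytic demonstrator** that solves for the optimal actions against
  the ground truth (ICP-style correspondence refinement; the deformation is
  the exact solution of a graph-Laplacian-regularized least-squares system),
- **DAGGER** imitation learning of the actor on demonstrator labels
  aggregated along learner-visited states,
- **DDPG** joint training, where the value network learns a double-DQN
  bootstrap target with an epsilon-greedy behaviour policy and the actor is
  refined at a slower rate through the value network's gradient,
- **CPD/SSM augmentation**: a statistical shape model built by iterative
  coherent-point-drift template registration generates realistic training
  shapes, and
- a **synthetic phantom generator** (blob organs with multi-modality
  appearance variants, anisotropic voxel spacings, smooth deformation fields
  with paired landmarks) so the whole system trains and verifies without
  clinical data.

The networks are PointNet-style (shared per-vertex dense blocks, max-pool
global feature, skip connections, multi-task heads) implemented in pure
numpy on a small reverse-mode autodiff engine (`actseg/autodiff.py`).

## CLI

```bash
actseg --seed 1 --out runs/ph phantom                       # synthetic case
actseg --seed 1 --out runs/agent train-agent --n-cases 8    # DAGGER + DDPG
actseg segment --volume v.nii.gz --template t.ply \
       --checkpoint runs/agent/agent.npz --out-mesh seg.ply
actseg --seed 1 --out runs/reg train-actor                  # non-rigid only
actseg register --volume v.nii.gz --landmarks lm.csv \
       --checkpoint runs/reg/actor.npz --out-landmarks out.csv
actseg evaluate --pred-mesh seg.ply --labels labels.nii.gz
actseg --out runs/beta beta-study --betas 0.5,1,2           # speed/accuracy
```

All geometry is in world mm (RAS+); the NIfTI affine is the single source of
geometric truth, so anisotropic voxel spacings need no resampling.

## Layout

| Module | Role |
| --- | --- |
| `actseg.geometry` | volumes, clouds, meshes, distances, kNN graphs, normals, world/voxel transforms, trilinear sampling |
| `actseg.observation` | per-vertex observation encoding (ray + patch modes, normalization) |
| `actseg.actions` | action model: raw / normalized / beta-scaled stages, application to clouds |
| `actseg.demonstrator` | optimal translation / scale / rotation / regularized deformation |
| `actseg.autodiff`, `actseg.networks` | numpy autodiff, actor & value networks, losses, checkpoints |
| `actseg.environment`, `actseg.training` | MDP environment, reward, DDQN targets and Q bounds, DAGGER, DDPG, replay |
| `actseg.shape_model` | nonrigid CPD, SSM construction, mesh augmentation |
| `actseg.inference` | greedy episodes, landmark registration, Dice / surface distance / TRE, beta-study harness |
| `actseg.phantoms` | seeded synthetic volumes, meshes, labels, deformation fixtures |
| `actseg.io`, `actseg.cli` | NIfTI / PLY / OBJ / CSV / YAML I/O and the command line |
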