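kind: sequencing
name: iseq100
read_length: 150
forward_mean_rate: 1.1e-3
reverse_mean_rate: 2.5e-3
indel_rate: 5.0e-5
pattern_weights_forward:
  "A>G/T>C": 0.27
  "C>T/G>A": 0.27
  "A>T/T>A": 0.17
pattern_weights_reverse:
  "A>G/T>C": 0.22
  "C>T/G>A": 0.22
  "A>T/T>A": 0.37
# per-cycle substitution-rate shape (mean 1), scaled to the configured
# direction means at load time; same curve for both read directions
profile_shape: [2.6480, 2.3227, 2.0475, 1.8144, 1.6172, 1.4502, 1.3089, 1.1893, 1.0880, 1.0023, 0.9297, 0.8683, 0.8163, 0.7723, 0.7350, 0.7035, 0.6768, 0.6542, 0.6351, 0.6189, 0.6118, 0.6069, 0.6037, 0.6021, 0.6017, 0.6024, 0.6041, 0.6065, 0.6095, 0.6131, 0.6172, 0.6217, 0.6265, 0.6316, 0.6369, 0.6425, 0.6482, 0.6540, 0.6600, 0.6661, 0.6723, 0.6785, 0.6848, 0.6912, 0.6976, 0.7041, 0.7106, 0.7171, 0.7236, 0.7302, 0.7368, 0.7433, 0.7499, 0.7566, 0.7632, 0.7698, 0.7764, 0.7831, 0.7897, 0.7964, 0.8030, 0.8097, 0.8163, 0.8230, 0.8296, 0.8363, 0.8429, 0.8496, 0.8563, 0.8629, 0.8696, 0.8762, 0.8829, 0.8896, 0.8962, 0.9029, 0.9096, 0.9162, 0.9229, 0.9296, 0.9362, 0.9429, 0.9496, 0.9562, 0.9629, 0.9696, 0.9762, 0.9829, 0.9896, 0.9962, 1.0029, 1.0096, 1.0162, 1.0229, 1.0296, 1.0362, 1.0429, 1.0496, 1.0562, 1.0629, 1.0696, 1.0762, 1.0829, 1.0896, 1.0962, 1.1029, 1.1095, 1.1162, 1.1229, 1.1295, 1.1362, 1.1429, 1.1495, 1.1562, 1.1629, 1.1695, 1.1762, 1.1829, 1.1895, 1.1962, 1.2029, 1.2095, 1.2162, 1.2229, 1.2295, 1.2362, 1.2429, 1.2495, 1.2562, 1.2629, 1.2695, 1.2762, 1.2829, 1.2895, 1.2962, 1.3029, 1.3095, 1.3162, 1.3229, 1.3295, 1.3362, 1.3429, 1.3495, 1.3562, 1.3629, 1.3695, 1.3762, 1.3829, 1.3895, 1.3962]
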