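{
 "2,1": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8,
  9,
  10,
  11,
  12,
  13,
  14
 ],
 "2,2": [
  1,
  2,
  3,
  4,
  12,
  13
 ],
 "2,3": [
  1,
  2,
  3,
  4
 ],
 "3,1": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8,
  9,
  10,
  11
 ],
 "3,2": [
  1,
  2,
  3,
  4
 ],
 "3,3": [
  1,
  2,
  3,
  4
 ]
}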