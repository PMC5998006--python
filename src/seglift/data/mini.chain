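# miniature synthetic two-assembly chain set used in docs and tests
chain 100 chr1 1000 + 0 1000 chr1 1000 + 0 1000 1
1000

chain 90 chr1 1000 + 0 300 chrA 900 + 100 390 2
100	50	40
150

chain 80 chr2 500 + 0 100 chrB 1000 - 0 100 3
100

chain 70 chr3 2000 + 100 700 chr3 1800 + 50 610 4
200	100	60
300
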