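chr11	54526000	75256001	1
chr11	75256001	79404001	2
chr11	79404001	79816001	3
chr11	79816001	81783001	4
chr11	81783001	81826001	5
chr11	81826001	81900001	6
chr11	81900001	105587001	7
chr11	105587001	117653001	8
chr11	117653001	119635001	9
chr11	119635001	119932001	10
chr11	119932001	132956001	11
chr11	132956001	135087001	12
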