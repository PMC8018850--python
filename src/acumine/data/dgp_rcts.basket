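# Acupoint prescriptions from 17 randomized controlled trials of acupuncture
# for diabetic gastroparesis, one trial per line: "trial label: acupoints".
Wang et al. (2008): ST36,LI4
Ge et al. (2010): CV12,ST36,PC6
Shen et al. (2010): PC6,CV12,CV6,ST36,SP6
Wang et al. (2010): BL20,BL21,BL18,BL23,PC6,ST36,SP6,CV12
Zeng and Chai (2008): BL21,CV12,BL20,LR13,BL23,BL18,LR14,GB25,ST25,ST36
Zhang et al. (2007): CV12,ST36,PC6
Zheng and Ge (2010): CV12,ST36,PC6
Han et al. (2001): ST36,ST25,PC6,ST39,CV12
Li (2006): ST36,CV12,ST25,BL21,BL20,LR3,BL23,PC6
Wang (2007): BL21,CV12,BL20,LR13,BL23,BL18,LR14,GB25,ST25,ST36
Wang et al. (2009): CV17,CV13,CV12,CV4,CV10,CV8,CV6
Chen (2008): CV12,ST36,ST25,ST21,ST37
Zhao (2011): ST36,CV12,ST25,ST21,ST37
Chen (2005): CV12,ST21,ST25,BL21,ST36
Zhang et al. (2013): CV12,ST36,PC6
Li et al. (2015): CV12,ST36,PC6
Song et al. (2020): CV12,ST36,PC6,SP9,SP10,SP6,SP8,LI11,LI4,ST40,LR3,SP4
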