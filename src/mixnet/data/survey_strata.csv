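ecosystem,season,n_clusters,mean_cluster_size
TME,wet,858,1.223
TME,dry,438,1.243
SNE,wet,2324,1.346
SNE,dry,1783,1.291
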